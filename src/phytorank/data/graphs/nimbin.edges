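# nimbin: hydrogen-suppressed heavy-atom skeleton (C30H36O9)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 C2
C2 O3
C2 O4
O4 C5
C5 C6
C6 C7
C6 C8
C8 C9
C9 C10
C10 C11
C11 C12
C12 C13
C13 C14
C14 O15
O15 C16
C11 C17
C17 C18
C17 C19
C19 C20
C20 C21
C21 O22
C21 O23
O23 C24
C20 C25
C25 C26
C26 C27
C26 C28
C28 O29
O29 C30
C30 C31
C31 O32
C31 C33
C33 C34
C34 O35
C34 O36
O36 C37
C33 C38
C38 C39
C39 C5
C25 C6
C17 C8
C16 C12
C38 C26
C30 C28
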