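# nimbolide: hydrogen-suppressed heavy-atom skeleton (C27H30O7)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
O1 C2
C2 C3
C3 C4
C3 C5
C5 C6
C6 C7
C7 O8
C7 C9
C9 C10
C10 C11
C11 C12
C12 O13
O13 C14
C9 C15
C15 C16
C15 C17
C17 C18
C18 C19
C19 O20
C19 O21
O21 C22
C18 C23
C23 C24
C24 C25
C24 C26
C26 C27
C27 C28
C28 O29
C28 C30
C30 C31
C30 C32
C30 C33
C33 O34
O34 C2
C23 C3
C15 C5
C14 C10
C33 C24
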