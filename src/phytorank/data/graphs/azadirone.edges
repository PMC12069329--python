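# azadirone: hydrogen-suppressed heavy-atom skeleton (C28H36O4)
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
C21 C22
C22 C23
C22 C24
C24 C25
C25 C26
C26 O27
C26 C28
C28 C29
C28 C30
C28 C31
C31 C32
C32 C5
C21 C6
C17 C8
C16 C12
C31 C22
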