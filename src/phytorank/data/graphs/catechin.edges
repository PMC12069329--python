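# catechin: hydrogen-suppressed heavy-atom skeleton (C15H14O6)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
O1 C2
C2 C3
C3 C4
C4 O5
C4 C6
C6 C7
C7 C8
C7 O9
O9 C10
C10 C11
C11 C12
C12 C13
C13 C14
C14 O15
C14 C16
C16 O17
C16 C18
C10 C19
C19 O20
C19 C21
C8 C2
C18 C11
C21 C6
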