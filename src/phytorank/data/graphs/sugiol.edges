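# sugiol: hydrogen-suppressed heavy-atom skeleton (C20H28O2)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 C2
C2 C3
C2 C4
C4 C5
C5 C6
C6 C7
C7 C8
C8 C9
C9 O10
C7 C11
C11 C12
C11 C13
C13 C14
C14 C15
C15 C16
C16 C17
C16 C18
C16 C19
C19 C20
C20 C21
C21 O22
C9 C4
C19 C11
C21 C6
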