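# scopoletin: hydrogen-suppressed heavy-atom skeleton (C10H8O4)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 O2
O2 C3
C3 C4
C4 C5
C5 C6
C6 C7
C7 C8
C8 O9
C8 O10
O10 C11
C11 C12
C12 C13
C13 O14
C13 C3
C11 C5
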