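# tiglic_acid: hydrogen-suppressed heavy-atom skeleton (C5H8O2)
# 2-methyl-2-butenoic acid, CH3-CH=C(CH3)-COOH; single edges regardless of bond order
C1 C2
C2 C3
C3 C4
C3 C5
C5 O1
C5 O2
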