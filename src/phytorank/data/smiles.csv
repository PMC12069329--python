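compound_id,smiles,formula
azadirone,CC(=O)OC1C2(C)C3=CCC(c4ccoc4)C3(C)CCC2C5(C)C=CC(=O)C(C)(C)C5C1,C28H36O4
azadirachtin,COC(=O)C1C2(O)CC(OC(=O)C(C)=CC)C3(C)C(O)C(O)C4(C(=O)OC)C5OC(C)=C6CC7(CO7)C6(O)C5(C=C(OC(C)=O)C34C)OC2(O)C1,C35H44O16
stigmasterol,CCC(C=CC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C)C(C)C,C29H48O
tiglic_acid,CC=C(C)C(=O)O,C5H8O2
catechin,Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2,C15H14O6
scopoletin,COc1cc2ccc(=O)oc2cc1O,C10H8O4
odoratone,CC(C=CC(O)C(C)(C)O)C1CCC2(C)C1(C)CCC1=C2CC(=O)C2C(C)(C)CCCC12C,C30H48O3
tirucallol,CC(CCC=C(C)C)C1CCC2(C)C1(C)CCC1=C2CCC2C(C)(C)C(O)CCC12C,C30H50O
nimbin,CC(=O)OC1C2(C)C3=CCC(c4ccoc4)C3(C)CC(C(=O)OC)C2C5(C)C6OC6C(=O)C(C(=O)OC)C5C1,C30H36O9
nimbolide,O=C1C2(C)C3=CC(O)C(c4ccoc4)C3(C)C=C(C(=O)OC)C2C5(C)C=CC(=O)C(C)(C)C5O1,C27H30O7
sugiol,CC(C)c1cc2c(cc1O)C1(C)CCCC(C)(C)C1CC2=O,C20H28O2
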