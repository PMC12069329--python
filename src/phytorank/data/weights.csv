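criterion,weight
ABC,0.2
AUZ,0.1
RLI,0.3
SLI,0.1
MDI,0.2
ISLI,0.1
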