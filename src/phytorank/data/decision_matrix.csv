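compound_id,ABC,AUZ,RLI,SLI,MDI,ISLI
azadirone,25.983,301.78,27.3274,64.193,44,21.547
azadirachtin,40.875,542.53,44.4979,99.675,68,35.887
stigmasterol,23.67,271.2,25.6985,50.483,40,20.273
tiglic_acid,4.53,37.516,1.6684,7.9502,8,4.8263
catechin,16.647,174.44,20.7007,39.726,23,11.686
scopoletin,10.744,97.656,9.7478,25.705,13,10.646
odoratone,27.692,381.57,31.1197,58.012,54,24.777
tirucallol,30.342,278.09,24.5695,59.16,42,17.359
nimbin,29.388,350.3,32.2078,73.497,52,24.929
nimbolide,27.275,270,31.4463,70.153,40,22.897
sugiol,17.538,187.65,16.8485,41.18,30,15.01
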