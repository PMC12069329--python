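compound_id,ISI,MDI,MMRDI,ISLI,ABC,M1,RLI,SLI,AUZ,MLI
azadirone,43.845,44,47.664,21.547,25.983,198,27.3274,64.193,301.78,18.6562
azadirachtin,70.2026,68,76.437,35.887,40.875,306,44.4979,99.675,542.53,29.7
stigmasterol,38.99,40,42.897,20.273,23.67,168,25.6985,50.483,271.2,14.8535
tiglic_acid,5.7,8,9.4282,4.8263,4.53,26,1.6684,7.9502,37.516,4.7998
catechin,26.35,23,29.582,11.686,16.647,114,20.7007,39.726,174.44,10.7632
scopoletin,16.9667,13,16.901,10.646,10.744,72,9.7478,25.705,97.656,6.5392
odoratone,53.8,54,45.083,24.777,27.692,208,31.1197,58.012,381.57,20.977
tirucallol,40.6857,42,53.359,17.359,30.342,180,24.5695,59.16,278.09,17.96915
nimbin,50.547,52,53.283,24.929,29.388,209,32.2078,73.497,350.3,19.0154
nimbolide,48.5143,40,49.691,22.897,27.275,237,31.4463,70.153,270,17.1059
sugiol,28.4089,30,33.205,15.01,17.538,118,16.8485,41.18,187.65,13.2349
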