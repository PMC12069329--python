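compound_id,enthalpy_of_vaporization,boiling_point,polarizability,molar_refractivity,monoisotopic_mass
azadirone,77.6,506,49,123.7,436.26
azadirachtin,131.3,792.4,66.6,168,720.26
stigmasterol,88.7,501.1,51.2,129.1,412.37
tiglic_acid,47.9,198.5,10.6,26.7,100.05
catechin,—,630.4,29.2,73.6,290.08
scopoletin,69.2,413.5,19.2,48.3,192.04
odoratone,98.4,571.2,53.6,135.2,472.36
tirucallol,88.3,498.9,52.9,133.4,426.39
nimbin,90.1,606.1,54.8,138.1,540.24
nimbolide,90.4,608.6,47.7,120.4,466.2
sugiol,72.1,437.2,35.5,89.7,300.21
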