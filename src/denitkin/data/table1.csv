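# In-vitro run matrix (series A-E). Concentrations as charged:
# no3_mmol [mmol/dm3]; microorganism inoculum and electron donor in
# mg/dm3 (humic acid doses are mg/dm3 as carbon). Temperature 35 C,
# argon headspace throughout. duration_d gives the sampling window.
series,run,method,ph,no3_mmol,sludge_mg,azoarcus_mg,glucose_mg,plasticizer_mg,humic_mix_mgC,humic_na_mgC,duration_d
A,1,ampule,7,20,1000,,,0,,,50
A,2,ampule,7,20,1000,,,3000,,,50
B,3,ampule,8,10,1000,,,,100,,10
B,4,ampule,8,50,1000,,,,100,,10
B,5,vial,8,10,1000,,,,1,,30
B,6,vial,8,10,1000,,,,10,,30
B,7,vial,8,10,1000,,,,100,,30
C,8,ampule,8,50,,1000,,,,0,11
C,9,ampule,8,50,,1000,,,,10,11
C,10,ampule,8,50,,1000,,,,100,11
C,11,ampule,8,50,,1000,,,,1000,11
D,12,vial,8,50,,1000,100,,,,7
D,13,vial,8,50,,1000,,,,100,7
E,14,vial,8,10,10,,,,,0,50
E,15,vial,8,10,10,,,,,10,50
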