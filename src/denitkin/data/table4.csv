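# In-situ flow-cell chemistry: nitrogen species in the circulating solution.
# Units: time_d [d]; no3_mmol, no2_mmol, nh3_mmol [mmol/dm3].
# S-1 was sampled before the nitrate + organics injection.
sample_id,time_d,no3_mmol,no2_mmol,nh3_mmol
S-1,0,0.000013,0.000012,0.00200
S-2,0.9,9.05,0.0056,0.00078
S-3,3.9,9.05,0.0051,0.00027
S-4,8.9,8.79,0.0043,0.00028
S-5,17,7.95,0.0016,0.00018
S-6,31,7.69,0.0044,0.00048
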