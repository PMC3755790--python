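# Prepared in-situ dataset: model-ready trajectory.
# Units: toc_gC [g-C/dm3]; tnc_solution_dm3, cells_total [cells/dm3];
# biomass_toc [g-TOC/dm3]; no3_gN [g-N/dm3].
# S-1 (pre-injection) has no biomass_toc / no3_gN entries.
sample_id,time_d,toc_gC,tnc_solution_dm3,cells_total,biomass_toc,no3_gN
S-1,0.0,0.0004,1.30E+08,2.42E+10,,
S-2,0.9,0.190,1.84E+08,2.09E+10,1.22E-03,0.125
S-3,3.9,0.194,1.15E+09,4.21E+10,2.46E-03,0.125
S-4,8.9,0.191,2.20E+09,4.58E+10,2.67E-03,0.122
S-5,18.0,0.185,2.86E+09,6.91E+10,4.03E-03,0.115
S-6,31.0,0.180,3.41E+09,1.68E+11,9.82E-03,0.113
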