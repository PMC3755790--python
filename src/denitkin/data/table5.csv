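# In-situ flow-cell microbiology: direct counts and NarG qPCR.
# Units: tnc_solution [cells/cm3] with sigma (n=3); qpcr_solution and
# qpcr_biofilm [NarG copies/g] with sigmas (n=4 and n=8 or 16).
sample_id,time_d,tnc_solution,tnc_sigma,qpcr_solution,qpcr_solution_sigma,qpcr_biofilm,qpcr_biofilm_sigma
S-1,0,130,32,3.94E05,2.27E05,2.26E08,1.85E08
S-2,0.9,190,54,3.63E05,1.17E05,1.95E08,7.70E07
S-3,3.9,1400,99,7.98E05,3.12E05,3.93E08,3.53E08
S-4,8.9,2900,140,8.93E05,7.41E05,4.27E08,3.22E08
S-5,17,4000,1300,3.37E06,2.19E06,6.32E08,2.72E08
S-6,31,5100,710,4.31E07,2.84E07,1.35E09,7.55E08
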