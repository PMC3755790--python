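# Experiment-wide "increase of amount" row of the prepared dataset, as
# printed: delta_toc [g-C/dm3], delta_cells [cells/dm3],
# delta_biomass_toc [g-TOC/dm3], delta_no3 [g-N/dm3].
delta_toc,delta_cells,delta_biomass_toc,delta_no3
-0.014,1.22E+11,8.60E-03,-0.012
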