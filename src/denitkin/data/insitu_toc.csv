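# Solution TOC series for the in-situ experiment [g-C/dm3].
sample_id,toc_gC
S-1,0.0004
S-2,0.190
S-3,0.194
S-4,0.191
S-5,0.185
S-6,0.180
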