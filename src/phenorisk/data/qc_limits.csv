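analyte,lod_mg_L,loq_mg_L,mdl_mg_L,r_squared
BPA,0.33,1.08,0.25,0.9983
HQ,0.34,1.13,0.26,0.9981
RE,0.43,1.41,0.32,0.9978
BQ,0.19,0.61,0.15,0.9996
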