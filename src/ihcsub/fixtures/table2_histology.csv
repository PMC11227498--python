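level,classical,transitional,basal_like
glandular,61,73,0
por_comp,24,12,4
sq_diff,0,0,16
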