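level,classical,transitional,basal_like
M,44,45,7
F,41,40,13
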