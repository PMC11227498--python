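level,classical,transitional,basal_like
I,8,7,0
II,13,8,2
III,17,14,6
IV,42,53,12
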