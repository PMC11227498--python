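level,classical,transitional,basal_like
<70,38,42,6
>=70,47,43,14
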