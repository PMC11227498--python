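marker,grade0,grade1,grade2,grade3
CK56,146,21,9,14
P63,125,43,14,8
GATA6,2,13,60,115
HNF4A,28,31,65,66
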