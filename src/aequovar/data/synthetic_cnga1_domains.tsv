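domain	aa_start	aa_end
TD1	255	300
TD2	310	335
pore	380	410
TD6	415	440
C-linker	445	490
CNBD	491	610
CLZ	620	686
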