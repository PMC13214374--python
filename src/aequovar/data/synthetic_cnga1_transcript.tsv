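exon_label	length_nt	coding_overlap_nt
1	100	0
2	90	0
3	120	0
4	170	120
5	150	150
6	180	180
7	210	210
8	120	120
9	108	108
10	100	100
11	2000	1073
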