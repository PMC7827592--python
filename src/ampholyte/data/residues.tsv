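# code	name	pKA	group_type	bond_length_nm
D	aspartic acid	3.65	acid	0.327
E	glutamic acid	4.25	acid	0.436
H	histidine	6.0	base	0.453
Y	tyrosine	10.07	acid	0.648
K	lysine	10.54	base	0.589
a	hypothetical acid	6.0	acid	0.355
b	hypothetical base	6.0	base	0.355
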