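# source: Bjellqvist pKa set (ProtParam)
group	pka
Cterm	3.55
Nterm_A	7.59
Nterm_E	7.7
Nterm_G	7.5
Nterm_M	7.0
Nterm_P	8.36
Nterm_S	6.93
Nterm_T	6.82
Nterm_V	7.44
Nterm_default	7.5
side_C	9.0
side_D	4.05
side_E	4.45
side_H	5.98
side_K	10.0
side_R	12.0
side_Y	10.0
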