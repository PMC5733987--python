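# source: Ikai 1980 aliphatic index coefficients
name	value
val_coeff	2.9
ile_leu_coeff	3.9
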