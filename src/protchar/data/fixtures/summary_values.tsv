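# published whole-protein summary values; printed = as printed, corrected = arithmetic-consistent overlay
protein	metric	printed	corrected
3K4Q	mw_kda	48.84	48.84
1QFX	mw_kda	58.78	50.78
3K4Q	pi	4.94	4.94
1QFX	pi	4.60	4.60
3K4Q	gravy	-0.304	-0.304
1QFX	gravy	-0.330	-0.330
3K4Q	aliphatic_index	72.25	72.25
1QFX	aliphatic_index	70.46	70.46
3K4Q	instability_index	45.41	45.41
1QFX	instability_index	33.66	33.66
3K4Q	mean_antigenic_propensity	1.0304	1.0304
1QFX	mean_antigenic_propensity	1.0234	1.0234
3K4Q	nterm_residue	A	A
1QFX	nterm_residue	F	F
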