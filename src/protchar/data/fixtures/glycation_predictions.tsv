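# sequence-based external glycation predictor calls per lysine (1 = predicted glycable)
protein	lysine	external
3K4Q	68	1
3K4Q	70	0
3K4Q	71	1
3K4Q	89	1
3K4Q	94	0
3K4Q	119	0
3K4Q	148	0
3K4Q	149	1
3K4Q	158	1
3K4Q	160	1
3K4Q	172	1
3K4Q	254	0
3K4Q	277	0
3K4Q	278	0
3K4Q	356	0
1QFX	14	1
1QFX	28	0
1QFX	61	0
1QFX	74	0
1QFX	82	0
1QFX	92	0
1QFX	134	0
1QFX	163	0
1QFX	217	0
1QFX	285	0
1QFX	307	1
1QFX	413	1
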