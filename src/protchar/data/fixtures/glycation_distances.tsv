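# per-lysine printed distances between Lys eps-NH2 and acidic/basic side chains
# bound: exact = printed distance; gt = printed lower bound (no partner within it)
protein	lysine	partner_kind	partner	distance	bound
3K4Q	68	acid	Glu205	8.26	exact
3K4Q	68	base	Lys70	6.51	exact
3K4Q	70	acid	Asp66	4.09	exact
3K4Q	70	base	Lys71	9.05	exact
3K4Q	70	base	Lys68	6.51	exact
3K4Q	71	acid	Glu233	9.89	exact
3K4Q	89	acid	Asp223	5.68	exact
3K4Q	94	acid	-	13.98	gt
3K4Q	94	base	-	13.06	gt
3K4Q	119	acid	Asp405	4.21	exact
3K4Q	119	acid	Asp12	4.27	exact
3K4Q	148	base	Lys149	9.73	exact
3K4Q	149	acid	Glu152	4.52	exact
3K4Q	158	acid	Asp161	7.65	exact
3K4Q	160	acid	Asp161	9.97	exact
3K4Q	172	acid	Asp174	4.50	exact
3K4Q	254	acid	Asp244	9.84	exact
3K4Q	277	acid	Asp239	7.30	exact
3K4Q	277	acid	Asp202	9.16	exact
3K4Q	277	acid	Glu205	4.28	exact
3K4Q	277	base	Lys68	7.84	exact
3K4Q	277	base	Lys278	6.72	exact
3K4Q	278	base	Lys277	6.72	exact
3K4Q	278	base	His282	6.51	exact
3K4Q	356	acid	Asp370	8.5	exact
3K4Q	356	acid	Glu364	9.83	exact
1QFX	14	acid	Glu19	8.26	exact
1QFX	28	acid	Glu38	8.55	exact
1QFX	28	acid	Asp22	6.95	exact
1QFX	28	base	His29	8.6	exact
1QFX	61	acid	Asp125	6.56	exact
1QFX	61	base	His360	4.63	exact
1QFX	61	base	His129	4.40	exact
1QFX	74	acid	Glu77	9.04	exact
1QFX	74	acid	Glu78	4.51	exact
1QFX	74	acid	Asp75	5.95	exact
1QFX	82	acid	Glu78	9.46	exact
1QFX	82	acid	Asp236	4.15	exact
1QFX	92	acid	Glu90	4.61	exact
1QFX	134	base	His139	9.21	exact
1QFX	163	acid	Glu159	8.49	exact
1QFX	163	acid	Glu166	4.74	exact
1QFX	163	base	Arg447	9.84	exact
1QFX	217	acid	-	11.97	gt
1QFX	217	base	-	13.15	gt
1QFX	285	acid	Glu284	7.35	exact
1QFX	307	acid	Glu308	9.81	exact
1QFX	413	acid	-	29.31	gt
1QFX	413	base	-	23.84	gt
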