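# published N-glycosylation sequon positions and 4-residue contexts
protein	position	context
3K4Q	27	NQSS
3K4Q	59	NESV
3K4Q	105	NATT
3K4Q	120	NYSL
3K4Q	207	NNTL
3K4Q	230	NFTA
3K4Q	339	NHTL
3K4Q	352	NSTL
3K4Q	376	NGTK
3K4Q	388	NITQ
1QFX	87	NTTE
1QFX	172	NYST
1QFX	208	NLTY
1QFX	231	NLTA
1QFX	296	NASL
1QFX	321	NITP
1QFX	406	NYTS
1QFX	423	NVSA
1QFX	439	NTTT
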