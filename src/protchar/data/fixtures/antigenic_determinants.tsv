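# published antigenic determinant fragments (mature numbering)
protein	fragment	start	sequence	end	length
3K4Q	1	23	HLWGQYAPFFSLANESVISPEVPAGCRVTFAQVLSR	58	36
3K4Q	2	374	SAWTVPFASRLYVEMMQCQAEQEPLVRVLVNDRVVPLHGCPVDALGR	420	47
1QFX	1	322	ITPILAALGVLIPNE	336	15
1QFX	2	378	TYVRLVLNEAVLPFN	392	15
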