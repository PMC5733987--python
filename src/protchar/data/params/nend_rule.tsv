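# source: N-end rule half-lives (ProtParam tabulation)
residue	mammalian_in_vitro	yeast_in_vivo	ecoli_in_vivo
A	4.4 hours	>20 hours	>10 hours
C	1.2 hours	>20 hours	>10 hours
D	1.1 hours	3 min	>10 hours
E	1 hour	30 min	>10 hours
F	1.1 hours	3 min	2 min
G	30 hours	>20 hours	>10 hours
H	3.5 hours	10 min	>10 hours
I	20 hours	30 min	>10 hours
K	1.3 hours	3 min	2 min
L	5.5 hours	3 min	2 min
M	30 hours	>20 hours	>10 hours
N	1.4 hours	3 min	>10 hours
P	>20 hours	>20 hours	?
Q	0.8 hour	10 min	>10 hours
R	1 hour	2 min	2 min
S	1.9 hours	>20 hours	>10 hours
T	7.2 hours	>20 hours	>10 hours
V	100 hours	>20 hours	>10 hours
W	2.8 hours	3 min	2 min
Y	2.8 hours	10 min	2 min
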