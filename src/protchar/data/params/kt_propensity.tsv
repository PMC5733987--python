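# source: Kolaskar & Tongaonkar 1990 antigenic propensity
residue	propensity
A	1.064
C	1.412
D	0.866
E	0.851
F	1.091
G	0.874
H	1.105
I	1.152
K	0.93
L	1.25
M	0.826
N	0.776
P	1.064
Q	1.015
R	0.873
S	1.012
T	0.909
V	1.383
W	0.893
Y	1.161
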