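# source: Janin 1978 percent accessible residues
residue	value
A	6.6
C	0.9
D	7.7
E	5.7
F	2.4
G	6.7
H	2.5
I	2.8
K	10.3
L	4.8
M	1.0
N	6.7
P	4.8
Q	5.2
R	4.5
S	9.4
T	7.0
V	4.5
W	1.4
Y	5.1
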