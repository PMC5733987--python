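# mature 3-phytase A (PDB 3K4Q), 444 residues
residue	count
A	29
R	19
N	19
D	29
C	10
Q	19
E	22
G	30
H	9
I	18
L	36
K	15
M	4
F	25
P	22
S	49
T	39
W	4
Y	18
V	28
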