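# mature 3-phytase B chain A (PDB 1QFX), 460 residues
residue	count
A	40
R	14
N	38
D	24
C	10
Q	14
E	24
G	37
H	6
I	19
L	36
K	13
M	7
F	20
P	27
S	34
T	32
W	6
Y	35
V	24
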