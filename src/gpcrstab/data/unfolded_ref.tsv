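# Per-residue unfolded-state reference energies (kcal/mol):
# the surrogate's solvation term for an isolated, fully exposed
# residue in the same coarse side-chain representation the folded
# state uses (extended Gly-X-Gly-like context).
aa	energy
A	-3.6444
C	-3.5541
D	-3.4676
E	-3.3632
F	-3.3400
G	-5.7147
H	-3.3632
I	-3.4589
K	-3.2268
L	-3.4734
M	-3.4212
N	-3.4676
P	-3.6184
Q	-3.3632
R	-3.2012
S	-3.6184
T	-3.6184
V	-3.5541
W	-3.2123
Y	-3.2268
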