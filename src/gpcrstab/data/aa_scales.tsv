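# Per-residue sequence descriptors.
# hydrophobicity: Kyte-Doolittle (1982); polarity: Grantham (1974);
# charge: formal side-chain charge at pH 7; volume: Zamyatnin (1972), A^3;
# asa_ref: Tien et al. (2013) theoretical maximum accessible surface, A^2;
# polarizability: Charton & Charton (1982).
aa	hydrophobicity	polarity	charge	volume	asa_ref	polarizability
A	1.8	8.1	0	88.6	129.0	0.046
C	2.5	5.5	0	108.5	167.0	0.128
D	-3.5	13.0	-1	111.1	193.0	0.105
E	-3.5	12.3	-1	138.4	223.0	0.151
F	2.8	5.2	0	189.9	240.0	0.290
G	-0.4	9.0	0	60.1	104.0	0.000
H	-3.2	10.4	0	153.2	224.0	0.230
I	4.5	5.2	0	166.7	197.0	0.186
K	-3.9	11.3	1	168.6	236.0	0.219
L	3.8	4.9	0	166.7	201.0	0.186
M	1.9	5.7	0	162.9	224.0	0.221
N	-3.5	11.6	0	114.1	195.0	0.134
P	-1.6	8.0	0	112.7	159.0	0.131
Q	-3.5	10.5	0	143.8	225.0	0.180
R	-4.5	10.5	1	173.4	274.0	0.291
S	-0.8	9.2	0	89.0	155.0	0.062
T	-0.7	8.6	0	116.1	172.0	0.108
V	4.2	5.9	0	140.0	174.0	0.140
W	-0.9	5.4	0	227.8	285.0	0.409
Y	-1.3	6.2	0	193.6	263.0	0.298
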