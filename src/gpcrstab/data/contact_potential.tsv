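# Residue-pair contact energies (kcal/mol) applied per Cbeta-Cbeta
# contact < 8 A. Surrogate statistical term derived from the
# Kyte-Doolittle scale: e_ij = -0.10 * (h_i/4.5) * (h_j/4.5).
aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.016	-0.0222	0.0311	0.0311	-0.0249	0.0036	0.0284	-0.04	0.0347	-0.0338	-0.0169	0.0311	0.0142	0.0311	0.04	0.0071	0.0062	-0.0373	0.008	0.0116
C	-0.0222	-0.0309	0.0432	0.0432	-0.0346	0.0049	0.0395	-0.0556	0.0481	-0.0469	-0.0235	0.0432	0.0198	0.0432	0.0556	0.0099	0.0086	-0.0519	0.0111	0.016
D	0.0311	0.0432	-0.0605	-0.0605	0.0484	-0.0069	-0.0553	0.0778	-0.0674	0.0657	0.0328	-0.0605	-0.0277	-0.0605	-0.0778	-0.0138	-0.0121	0.0726	-0.0156	-0.0225
E	0.0311	0.0432	-0.0605	-0.0605	0.0484	-0.0069	-0.0553	0.0778	-0.0674	0.0657	0.0328	-0.0605	-0.0277	-0.0605	-0.0778	-0.0138	-0.0121	0.0726	-0.0156	-0.0225
F	-0.0249	-0.0346	0.0484	0.0484	-0.0387	0.0055	0.0442	-0.0622	0.0539	-0.0525	-0.0263	0.0484	0.0221	0.0484	0.0622	0.0111	0.0097	-0.0581	0.0124	0.018
G	0.0036	0.0049	-0.0069	-0.0069	0.0055	-0.0008	-0.0063	0.0089	-0.0077	0.0075	0.0038	-0.0069	-0.0032	-0.0069	-0.0089	-0.0016	-0.0014	0.0083	-0.0018	-0.0026
H	0.0284	0.0395	-0.0553	-0.0553	0.0442	-0.0063	-0.0506	0.0711	-0.0616	0.06	0.03	-0.0553	-0.0253	-0.0553	-0.0711	-0.0126	-0.0111	0.0664	-0.0142	-0.0205
I	-0.04	-0.0556	0.0778	0.0778	-0.0622	0.0089	0.0711	-0.1	0.0867	-0.0844	-0.0422	0.0778	0.0356	0.0778	0.1	0.0178	0.0156	-0.0933	0.02	0.0289
K	0.0347	0.0481	-0.0674	-0.0674	0.0539	-0.0077	-0.0616	0.0867	-0.0751	0.0732	0.0366	-0.0674	-0.0308	-0.0674	-0.0867	-0.0154	-0.0135	0.0809	-0.0173	-0.025
L	-0.0338	-0.0469	0.0657	0.0657	-0.0525	0.0075	0.06	-0.0844	0.0732	-0.0713	-0.0357	0.0657	0.03	0.0657	0.0844	0.015	0.0131	-0.0788	0.0169	0.0244
M	-0.0169	-0.0235	0.0328	0.0328	-0.0263	0.0038	0.03	-0.0422	0.0366	-0.0357	-0.0178	0.0328	0.015	0.0328	0.0422	0.0075	0.0066	-0.0394	0.0084	0.0122
N	0.0311	0.0432	-0.0605	-0.0605	0.0484	-0.0069	-0.0553	0.0778	-0.0674	0.0657	0.0328	-0.0605	-0.0277	-0.0605	-0.0778	-0.0138	-0.0121	0.0726	-0.0156	-0.0225
P	0.0142	0.0198	-0.0277	-0.0277	0.0221	-0.0032	-0.0253	0.0356	-0.0308	0.03	0.015	-0.0277	-0.0126	-0.0277	-0.0356	-0.0063	-0.0055	0.0332	-0.0071	-0.0103
Q	0.0311	0.0432	-0.0605	-0.0605	0.0484	-0.0069	-0.0553	0.0778	-0.0674	0.0657	0.0328	-0.0605	-0.0277	-0.0605	-0.0778	-0.0138	-0.0121	0.0726	-0.0156	-0.0225
R	0.04	0.0556	-0.0778	-0.0778	0.0622	-0.0089	-0.0711	0.1	-0.0867	0.0844	0.0422	-0.0778	-0.0356	-0.0778	-0.1	-0.0178	-0.0156	0.0933	-0.02	-0.0289
S	0.0071	0.0099	-0.0138	-0.0138	0.0111	-0.0016	-0.0126	0.0178	-0.0154	0.015	0.0075	-0.0138	-0.0063	-0.0138	-0.0178	-0.0032	-0.0028	0.0166	-0.0036	-0.0051
T	0.0062	0.0086	-0.0121	-0.0121	0.0097	-0.0014	-0.0111	0.0156	-0.0135	0.0131	0.0066	-0.0121	-0.0055	-0.0121	-0.0156	-0.0028	-0.0024	0.0145	-0.0031	-0.0045
V	-0.0373	-0.0519	0.0726	0.0726	-0.0581	0.0083	0.0664	-0.0933	0.0809	-0.0788	-0.0394	0.0726	0.0332	0.0726	0.0933	0.0166	0.0145	-0.0871	0.0187	0.027
W	0.008	0.0111	-0.0156	-0.0156	0.0124	-0.0018	-0.0142	0.02	-0.0173	0.0169	0.0084	-0.0156	-0.0071	-0.0156	-0.02	-0.0036	-0.0031	0.0187	-0.004	-0.0058
Y	0.0116	0.016	-0.0225	-0.0225	0.018	-0.0026	-0.0205	0.0289	-0.025	0.0244	0.0122	-0.0225	-0.0103	-0.0225	-0.0289	-0.0051	-0.0045	0.027	-0.0058	-0.0083
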