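position	mutation	role	exemplar_structures
2.50	D->N	Sodium pocket	AA2AR (5WF5)
3.39	S->A	Sodium pocket	AA2AR (5WF6)
3.40	I->V, A	P-I-F microswitch motif	ADRB1 (4BVN), APJ (5VBL)
3.41	X->W	stabilization of TM3, TM4, TM5 interface	5HT2B (4IB4), 5HT1B (4IAR), ADRB1 (5A8E), ADRB2 (3NY8), CXCR4 (3ODU), DRD3 (3PBL)
3.49	D,G->A	DRY motif	FFAR1 (5TZR), NTR1 (4XES)
5.58	Y->A	Conserved activation microswitch	FFAR1 (5TZR), ADRB1 (4BVN)
6.37	L->A	Interferes with DRY motif function	AA2AR (5IU4), NTR1 (4GRV)
7.49	D->N	Sodium pocket	P2RY1 (4XNV), P2Y12 (4PXZ)
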