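# Default ligand-contact table: (structure, generic position) pairs
# for commonly reported class-A orthosteric pocket positions.
# Curated default shipped with the package; user-overridable.
structure_id	generic_number
AA2AR	3.32
ADRB1	3.32
ADRB2	3.32
5HT1B	3.32
5HT2B	3.32
DRD3	3.32
CXCR4	3.32
M2R	3.32
M3R	3.32
H1R	3.32
ADRB1	3.33
ADRB2	3.33
5HT1B	3.33
5HT2B	3.33
DRD3	3.33
CXCR4	3.33
M2R	3.33
M3R	3.33
ADRB2	3.36
5HT1B	3.36
5HT2B	3.36
DRD3	3.36
CXCR4	3.36
M2R	3.36
M3R	3.36
H1R	3.36
OPRD	3.36
5HT1B	3.37
5HT2B	3.37
DRD3	3.37
CXCR4	3.37
M2R	3.37
M3R	3.37
H1R	3.37
5HT2B	5.42
DRD3	5.42
CXCR4	5.42
M2R	5.42
M3R	5.42
H1R	5.42
OPRD	5.42
OPRK	5.42
DRD3	5.43
CXCR4	5.43
M2R	5.43
M3R	5.43
H1R	5.43
OPRD	5.43
CXCR4	5.46
M2R	5.46
M3R	5.46
H1R	5.46
OPRD	5.46
OPRK	5.46
OPRM	5.46
M2R	6.48
M3R	6.48
H1R	6.48
OPRD	6.48
OPRK	6.48
OPRM	6.48
NTSR1	6.48
P2Y12	6.48
S1PR1	6.48
AA2AR	6.48
M3R	6.51
H1R	6.51
OPRD	6.51
OPRK	6.51
OPRM	6.51
NTSR1	6.51
P2Y12	6.51
S1PR1	6.51
AA2AR	6.51
ADRB1	6.51
H1R	6.52
OPRD	6.52
OPRK	6.52
OPRM	6.52
NTSR1	6.52
P2Y12	6.52
S1PR1	6.52
AA2AR	6.52
ADRB1	6.52
OPRD	6.55
OPRK	6.55
OPRM	6.55
NTSR1	6.55
P2Y12	6.55
S1PR1	6.55
AA2AR	6.55
ADRB1	6.55
OPRK	7.35
OPRM	7.35
NTSR1	7.35
P2Y12	7.35
S1PR1	7.35
AA2AR	7.35
OPRM	7.39
NTSR1	7.39
P2Y12	7.39
S1PR1	7.39
AA2AR	7.39
ADRB1	7.39
ADRB2	7.39
5HT1B	7.39
5HT2B	7.39
NTSR1	7.43
P2Y12	7.43
S1PR1	7.43
AA2AR	7.43
ADRB1	7.43
ADRB2	7.43
5HT1B	7.43
5HT2B	7.43
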