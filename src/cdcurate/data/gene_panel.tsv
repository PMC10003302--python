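symbol	transcript	chromosome	inheritance	pli	hotspot_codons	family_count	lof_mechanism
TGFBI	NM_000358.2	5	AD	0	124,555,626	1850	no
CHST6	NM_021615.4	16	AR	0	.	477	yes
SLC4A11	NM_032034.3	20	AR	0	.	199	yes
TACSTD2	NM_002353.2	1	AR	.	.	128	yes
ZEB1	NM_030751.5	10	AD	0.97	.	76	yes
UBIAD1	NM_013319.2	1	AD	.	.	74	no
KRT12	NM_000223.3	17	AD	.	.	31	no
COL8A2	NM_005202.3	1	AD	.	.	28	no
OVOL2	NM_021220.3	20	AD	.	.	23	no
PIKFYVE	NM_015040.3	2	AD	.	.	12	no
COL17A1	NM_000494.3	10	AD	.	.	12	no
GRHL2	NM_024915.3	8	AD	.	.	6	no
AGBL1	NM_152336.3	15	AD	.	.	8	no
DCN	NM_001920.4	12	AD	.	.	5	no
KRT3	NM_057088.2	12	AD	.	.	4	no
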