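gene	transcript	position	cdna	protein	n_families	n_alleles	gnomad_ac	gnomad_an	hgmd	novel	rank	evidence
TGFBI	NM_000358.2	135382095	c.370C>T	p.(Arg124Cys)	6	6	2	280458	DM	no	P	PS3+PM1+PM2+PP1+PP4
TGFBI	NM_000358.2	135382096	c.371G>A	p.(Arg124His)	8	8	10	249054	DM	no	P	PS3+PM1+PM2+PM5+PP1+PP4
TGFBI	NM_000358.2	135382096	c.371G>T	p.(Arg124Leu)	1	1	.	.	DM	no	P	PS4+PM1+PM5+PP1+PP4
TGFBI	NM_000358.2	135392469	c.1663C>T	p.(Arg555Trp)	3	3	.	.	DM	no	P	PS3+PS4+PM1+PP1+PP4
TGFBI	NM_000358.2	135392470	c.1664G>A	p.(Arg555Gln)	2	2	.	.	DM	no	P	PS3+PS4+PM1+PP1+PP4
TGFBI	NM_000358.2	135396596	c.1877A>G	p.(His626Arg)	1	1	.	.	DM	no	P	PS3+PS4+PP1+PP4
CHST6	NM_021615.4	75513232	c.495C>A	p.(Cys165*)	1	2	.	.	DM	no	P	PVS1+PS4+PM4+PP1+PP4
CHST6	NM_021615.4	75513095	c.632G>A	p.(Arg211Gln)	1	2	1	240952	DM	no	LP	PS4+PP1+PP2+PP3+PP4
CHST6	NM_021615.4	75513031	c.696G>A	p.(Trp232*)	2	2	1	237152	DM	no	P	PVS1+PS4+PM4+PP1+PP4
CHST6	NM_021615.4	75512924	c.803A>G	p.(Tyr268Cys)	23	25	20	275774	DM	no	LP	PM3+PP1+PP2+PP3+PP4
CHST6	NM_021615.4	75512835	c.892C>T	p.(Gln298*)	2	2	4	250212	DM	no	P	PVS1+PM2+PM4+PP1+PP4
CHST6	NM_021615.4	75512730	c.997T>G	p.(Trp333Gly)	2	2	.	.	DM?	no	LP	PS4+PP1+PP2+PP3+PP4
CHST6	NM_021615.4	75512631	c.1096G>T	p.(Glu366*)	1	1	.	.	.	yes	P	PVS1+PS4+PM4
SLC4A11	NM_032034.3	3218216	c.110C>A	p.(Ser37*)	1	1	4	251490	.	yes	P	PVS1+PM2+PM4
SLC4A11	NM_032034.3	3214820_3214827	c.473_480del	p.(Arg158Glnfs*4)	1	2	.	.	DM	no	P	PVS1+PS4+PM4
SLC4A11	NM_032034.3	3210194	c.1766dupA	p.(Tyr589*)	1	1	.	.	.	yes	P	PVS1+PS4+PM4
ZEB1	NM_030751.5	31809744_31809745	c.1481_1482insTTTT	p.(Lys494Asnfs*12)	1	1	.	.	.	yes	P	PVS1+PS4+PM4
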