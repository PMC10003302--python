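family_id	gene	allele1	allele2	phenotype
F1	TGFBI	c.370C>T	.	LCD
F2	TGFBI	c.370C>T	.	LCD
F3	TGFBI	c.370C>T	.	LCD
F4	TGFBI	c.370C>T	.	LCD
F5	TGFBI	c.370C>T	.	LCD
F6	TGFBI	c.370C>T	.	LCD
F7	TGFBI	c.371G>A	.	GCD2
F8	TGFBI	c.371G>A	.	GCD2
F9	TGFBI	c.371G>A	.	GCD2
F10	TGFBI	c.371G>A	.	GCD2
F11	TGFBI	c.371G>A	.	GCD2
F12	TGFBI	c.371G>A	.	GCD2
F13	TGFBI	c.371G>A	.	GCD2
F14	TGFBI	c.371G>A	.	GCD2
F15	TGFBI	c.371G>T	.	RBCD
F16	TGFBI	c.1663C>T	.	GCD1
F17	TGFBI	c.1663C>T	.	GCD1
F18	TGFBI	c.1663C>T	.	GCD1
F19	TGFBI	c.1664G>A	.	TBCD
F20	TGFBI	c.1664G>A	.	TBCD
F21	TGFBI	c.1877A>G	.	LCD
F22	CHST6	c.495C>A	c.495C>A	MCD
F23	CHST6	c.632G>A	c.632G>A	MCD
F24	CHST6	c.696G>A	c.997T>G	MCD
F25	CHST6	c.803A>G	c.1096G>T	MCD
F26	CHST6	c.803A>G	c.892C>T	MCD
F27	CHST6	c.803A>G	c.803A>G	MCD
F28	SLC4A11	c.110C>A	c.1766dupA	CHED
F29	SLC4A11	c.473_480del	c.473_480del	CHED
F30	ZEB1	c.1481_1482insTTTT	.	PPCD
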