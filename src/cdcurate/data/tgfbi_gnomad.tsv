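gene	cdna	protein	ac	an
TGFBI	c.337G>A	p.(Val113Ile)	38	280598
TGFBI	c.367G>C	p.(Asp123His)	38	280514
TGFBI	c.895G>A	p.(Asp299Asn)	131	279704
TGFBI	c.1501C>A	p.(Pro501Thr)	85	279506
TGFBI	c.1504A>G	p.(Met502Val)	494	279598
TGFBI	c.1631A>G	p.(Asn544Ser)	13	249042
TGFBI	c.1998G>C	p.(Arg666Ser)	244	213564
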