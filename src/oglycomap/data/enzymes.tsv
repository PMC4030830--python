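name	action	targets	anomer	linkage	terminal_only	notes
a-sialidase	remove	Neu5Ac	a	*	yes	broad sialidase (Arthrobacter ureafaciens type)
a2,3-sialidase	remove	Neu5Ac	a	2-3	yes	linkage-specific sialidase (Salmonella typhimurium type)
b-galactosidase	remove	Gal	b	*	yes	broad (jack bean type)
b1,3-galactosidase	remove	Gal	b	1-3	yes	linkage-specific
a-galactosidase	remove	Gal	a	*	yes	green coffee bean type
b-N-acetylhexosaminidase	remove	GlcNAc,GalNAc	b	*	yes	jack bean type; never removes the PA-tagged root
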