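rsid	gene	effect_allele	other_allele	eaf	weight	exposure
rs2282679	GC	C	A	0.28	-0.091	VITD
rs12794714	CYP2R1	A	G	0.32	-0.039	VITD
rs12785878	DHCR7	G	T	0.23	-0.042	VITD
rs1470579	IGF2BP2	C	A	0.30	0.113329	T2D
rs7903146	TCF7L2	T	C	0.30	0.223144	T2D
rs2237896	KCNQ1	A	G	0.22	0.398776	T2D
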