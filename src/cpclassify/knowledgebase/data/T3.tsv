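gene	cdna_hgvs	protein_hgvs	structural	mechanism	evidence_level	assay_notes	gpaf	af_afr	af_nfe	pathologically_relevant	gold_standard
PRSS1	triplication_CNV		true	GoF	experimental	increased_activation	Absent			true	true
PRSS1	duplication_CNV		true	GoF	experimental	increased_activation	Absent			true	true
PRSS1	double_GoF_CNV		true	GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.47C>T	p.Ala16Val		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.49C>A	p.Pro17Thr		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.56A>C	p.Asp19Ala		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.62A>C	p.Asp21Ala		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.65A>G	p.Asp22Gly		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.68A>G	p.Lys23Arg		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.63_71dup	p.Lys23_Ile24insIleAspLys		GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.86A>T	p.Asn29Ile		GoF	experimental	increased_activation|increased_stability	Absent			true	true
PRSS1	PRSS1-PRSS2_hybrid_1	p.Asn29Ile+p.Asn54Ser	true	GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.86A>C	p.Asn29Thr		GoF	experimental	increased_activation|increased_stability	Absent			true	true
PRSS1	PRSS1-PRSS2_hybrid_2	p.Asn29Ile+p.Asn54Ser	true	GoF	experimental	increased_activation	Absent			true	true
PRSS1	c.116T>C	p.Val39Ala		GoF	experimental	increased_stability	Absent			true	true
PRSS1	c.276G>T	p.Lys92Asn		GoF	experimental	increased_activation	0.000007953	0.00006152		true	true
PRSS1	c.364C>T	p.Arg122Cys		GoF	experimental	increased_activation	0.00001988		0.00003517	true	true
PRSS1	c.365G>A	p.Arg122His		GoF	experimental	increased_activation	0.00001194		0.00002639	true	true
PRSS1	c.365_366GC>AT	p.Arg122His		GoF	experimental	increased_activation	Absent			true	true
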