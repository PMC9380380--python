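gene	cdna_hgvs	protein_hgvs	structural	mechanism	loss_fraction	evidence_level	assay_notes	gpaf	af_eas	af_nfe	af_amr	n_families	pedigree_n_affected	pedigree_n_generations	pedigree_note	pathologically_relevant	mechanism_note
PRSS1	triplication_CNV		true	GoF		experimental		Absent				5	10	4	family with the most affected patients	true	GoF (gene dosage)
PRSS1	double_GoF_hybrid		true	GoF		experimental		Absent				1	6	3		true	GoF (gene dosage plus effect of p.Asn29Ile)
PRSS1	c.47C>T	p.Ala16Val		GoF		experimental	increased_activation	Absent				2	4	2		true	GoF (increased activation)
PRSS1	c.62A>C	p.Asp21Ala		GoF		experimental	increased_activation	Absent				1	5	3		true	GoF (increased activation)
PRSS1	c.63_71dup	p.Lys23_Ile24insIleAspLys		GoF		experimental	increased_activation	Absent				1	3	2		true	GoF (increased activation)
PRSS1	c.86A>T	p.Asn29Ile		GoF		experimental	increased_activation|increased_stability	Absent					19	7	second most frequent variant causing HCP	true	GoF (increased activation and stability)
PRSS1	c.86A>C	p.Asn29Thr		GoF		experimental	increased_activation|increased_stability	Absent				1	8	3		true	GoF (increased activation and stability)
PRSS1	c.116T>C	p.Val39Ala		GoF		experimental	increased_stability	Absent				1	9	3		true	GoF (increased stability)
PRSS1	c.311T>C	p.Leu104Pro		GoP		experimental	reduced_secretion|er_stress_marker	Absent				2	3	3	both families have 3 patients across 3 generations	true	GoP (intracellular retention and elevation of ER stress marker)
PRSS1	c.346C>T	p.Arg116Cys		GoP		experimental	reduced_secretion|er_stress_marker	0.00007072	0.0007018			2	3	3		true	GoP (intracellular retention and elevation of ER stress marker)
PRSS1	c.365G>A	p.Arg122His		GoF		experimental	increased_activation	0.00001194		0.00002639			20	4	most frequent variant causing HCP	true	GoF (increased activity)
PRSS1	c.365_366GC>AT	p.Arg122His		GoF		experimental	increased_activation	Absent				1	4	4		true	GoF (increased activity)
SPINK1	c.27delC	p.Ser10ValfsTer5		LoF	1.0	presumed_complete		0.00001197			0.00002896	1	3	2		true	LoF (predicted complete functional loss)
SPINK1	c.41T>G	p.Leu14Arg		LoF	1.0	experimental		Absent				2	3	3	both families have 3 patients across 3 generations	true	LoF (experimentally demonstrated to abolish SPINK1 secretion)
SPINK1	whole-gene_deletion		true	LoF	1.0	presumed_complete		Absent				1	3	2		true	LoF (predicted complete functional loss)
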