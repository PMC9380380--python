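gene	cdna_hgvs	protein_hgvs	structural	mechanism	evidence_level	assay_notes	gpaf	af_eas	pathologically_relevant	gold_standard
PRSS1	c.311T>C	p.Leu104Pro		GoP	experimental	reduced_secretion|er_stress_marker	Absent		true	true
PRSS1	c.346C>T	p.Arg116Cys		GoP	experimental	reduced_secretion|er_stress_marker	0.00007072	0.0007018	true	true
PRSS1	c.415T>A	p.Cys139Ser		GoP	experimental	reduced_secretion|er_stress_marker	Absent		true	true
PRSS1	c.416G>T	p.Cys139Phe		GoP	experimental	reduced_secretion|er_stress_marker	Absent		true	true
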