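gene	mrna_accession	year_discovered	coding_bp	protein_aa	mechanisms	oe_plof	oe_ci_low	oe_ci_high
PRSS1	NM_002769.5	1996	744	247	GoF|GoP	1.31	0.86	1.86
CFTR	NM_000492.4	1998	4443	1480	LoF	1.09	0.91	1.31
SPINK1	NM_001379610.1	2000	240	79	LoF	0.24	0.09	1.13
CTRC	NM_007272.3	2008	807	268	LoF|GoP	1.15	0.78	1.69
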