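gene	cdna_hgvs	protein_hgvs	mechanism	loss_fraction	evidence_level	assay_notes	legacy_category	gpaf	af_afr	af_eas	af_nfe	af_sas	or_point	or_ci_low	or_ci_high	or_context	pathologically_relevant	detection_note	mechanism_note	cf_category
PRSS1	c.623G>C	p.Gly208Ala	GoP		experimental	secretion_moderate_impact	pathogenic			0.00987			4.92			ICP	true	Asian population-specific variant, with an allele frequency of 0.009873 in East Asians	may predispose to CP through the misfolding pathway since it causes a moderate effect on secretion	
PRSS1	c.276G>T	p.Lys92Asn	GoP		experimental	secretion_moderate_impact|er_stress_untested	pathogenic	0.000007953	0.00006152								true		moderate impact on secretion; no data on ER stress	
PRSS1	c.372C>T	p.Ser124Ser	GoP		experimental	secretion_moderate_impact|er_stress_untested	pathogenic	Absent									true		moderate impact on secretion; no data on ER stress	
PRSS1	c.111C>A	p.Tyr37Ter	protective_LoF	1.0	presumed_complete		protective	Absent									false	a loss-of-function mutation that was found in normal controls		
PRSS1	c.200+1G>A		protective_LoF	1.0	presumed_complete		protective		0.02871								false	a loss-of-function mutation that was found in normal controls		
PRSS1	c.-204C>A		protective_LoF		experimental		protective	0.62		0.71	0.58		1.28			ICP	true	a common promoter polymorphism whose pathological authenticity is supported by both in silico and functional data; exerts a moderate genetic effect		
SPINK1	c.194+2T>C		LoF	0.90	experimental		pathogenic			0.003335			59.31	33.93	103.64	ICP	true		results in a ~90% functional loss of SPINK1	
SPINK1	c.101A>G	p.Asn34Ser	neutral	0.0	experimental		likely_benign										false		functionally neutral in all reported assays	
SPINK1	c.-4141G>T		LoF		experimental		likely_pathogenic					0.01975					true	functional enhancer variant in extensive linkage disequilibrium with p.Asn34Ser	reduces SPINK1 enhancer activity	
SPINK1	c.194G>A	p.Arg65Gln	LoF	0.50	experimental		pathogenic	Absent									true		causes a ~50% functional loss of SPINK1	
CFTR	c.1521_1523del	p.Phe508del	LoF	1.0	experimental		pathogenic						2.5	1.7	3.9	CP	true			cystic fibrosis-causing, severe
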