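gene	cdna_hgvs	protein_hgvs	structural	mechanism	loss_fraction	evidence_level	gpaf	af_amr	af_nfe	af_afr	af_eas	pathologically_relevant	gold_standard
SPINK1	c.-28211_*2066del		true	LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.-15969_*7702del		true	LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.-320_c.55+961del		true	LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.2T>G	p.Met1?		LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.2T>C	p.Met1?		LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.27delC	p.Ser10ValfsTer5		LoF	1.0	presumed_complete	0.00001197	0.00002896				true	true
SPINK1	c.55+1G>A			LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.87+1G>A			LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.98_99insA	p.Tyr33Ter		LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.177delG	p.Val60TyrfsTer35		LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.194+1G>A			LoF	1.0	presumed_complete	Absent					true	true
SPINK1	c.41T>C	p.Leu14Pro		LoF	1.0	experimental	Absent					true	true
SPINK1	c.41T>G	p.Leu14Arg		LoF	1.0	experimental	Absent					true	true
SPINK1	c.123G>C	p.Lys41Asn		LoF	1.0	experimental	Absent					true	true
SPINK1	c.143G>A	p.Gly48Glu		LoF	1.0	experimental	Absent					true	true
SPINK1	c.150T>G	p.Asp50Glu		LoF	1.0	experimental	0.000003991		0.000008834			true	true
SPINK1	c.160T>C	p.Tyr54His		LoF	1.0	experimental	Absent					true	true
SPINK1	c.190A>G	p.Asn64Asp		LoF	1.0	experimental	Absent					true	true
SPINK1	c.198A>C	p.Lys66Asn		LoF	1.0	experimental	0.0002272		0.0004129			true	true
SPINK1	c.199C>T	p.Arg67Cys		LoF	1.0	experimental	Absent					true	true
SPINK1	c.200G>A	p.Arg67His		LoF	1.0	experimental	0.003187			0.03078		true	true
SPINK1	c.206C>T	p.Thr69Ile		LoF	1.0	experimental	0.00001198				0.0001635	true	true
SPINK1	c.236G>T	p.Cys79Phe		LoF	1.0	experimental	Absent					true	true
SPINK1	c.*14_c.*15ins359		true	LoF	1.0	experimental	Absent					true	true
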