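gene	variant_label	category	detection_note	or_context	or_point	mechanism_note	protective
PRSS1	triplication_CNV	pathogenic	causes HCP; has also been noted in cases with FCP and ICP			causes the disease via a gene dosage effect	false
PRSS1	p.Ala16Val	pathogenic	highly variable penetrance			causes disease via the trypsin-dependent pathway	false
PRSS1	p.Arg122His	pathogenic	the most frequent variant found in HCP families			causes disease via the trypsin-dependent pathway	false
PRSS1	p.Gly208Ala	predisposing	Asian population-specific variant, with an allele frequency of 0.009873 in East Asians	ICP	4.92	may predispose to CP through the misfolding pathway since it causes a moderate effect on secretion	false
PRSS1	c.-204A>C	predisposing	a common promoter polymorphism whose pathological authenticity is supported by both in silico and functional data; exerts a moderate genetic effect	ICP	1.28		false
PRSS1	c.200+1G>A	benign	a loss-of-function mutation that was found in normal controls			protective against CP	true
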