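{
  "description": "Machine-readable copies of the published chronic-pancreatitis evidence tables bundled with cpclassify. All allele frequencies are gnomAD v2.1.1 (SVs v2.1) point estimates as printed in the source tables; no live database queries are performed.",
  "tables": {
    "T1.tsv": "Gene-level facts for the four CP genes: reference mRNA accession, functional categories of pathologically relevant variants, and gnomAD o/e score of pLoF variants with 95% CI.",
    "T2.tsv": "Very rare pathologically relevant variants found in hereditary CP (HCP) pedigrees: 12 PRSS1, 3 SPINK1, none in CFTR or CTRC. Pedigree columns give the family with the most affected patients.",
    "T3.tsv": "Gold-standard GoF variants in PRSS1 (19 records). The PRSS1-PRSS2 hybrid allele is printed twice in the source table and is retained as two records (hybrid_1/hybrid_2); the combined Tables 3-5 census of 47 records with 9 present in gnomAD depends on this count.",
    "T4.tsv": "Gold-standard GoP variants in PRSS1 (4 records).",
    "T5.tsv": "Gold-standard LoF variants in SPINK1 (24 records: 11 presumed complete loss, 13 experimentally demonstrated complete or almost complete loss). loss_fraction is uniformly encoded as 1.0 for 'complete or almost complete'. p.Arg67His (hspAF 0.03078, African/African American) is the documented outlier.",
    "T6.tsv": "Illustrative parenthetical qualifier components for PRSS1 variant annotations, decomposed into detection note, odds-ratio note and mechanism note.",
    "genes.json": "Gene-level evidence and per-gene classification policy for the four CP genes. ORs 2.7/5.3/15.6 (CFTR/CTRC/SPINK1) are aggregate values from a published German cohort; o/e values repeat T1.",
    "reclassification.tsv": "Inputs for the named reclassifications of PRSS1 and SPINK1 variants plus CFTR p.Phe508del. cDNA strings for p.Ser124Ser (c.372C>T) and p.Tyr37Ter (c.111C>A) were supplied from NM_002769.5 codon arithmetic, not printed in the source. The c.-204 promoter allele frequencies (0.62 global; 0.71 EAS / 0.58 NFE) are SYNTHETIC placeholders: the source only states the polymorphism is common, and the classification of the flipped risk allele depends only on hspAF >= 0.001. SPINK1 p.Asn34Ser frequencies are left unrecorded (its classification is frequency-independent)."
  },
  "notes": [
    "'Absent' cells mean the allele was not observed in gnomAD; empty cells mean not measured/not recorded.",
    "hspAF = highest subpopulation allele frequency; gpAF = global population allele frequency."
  ]
}
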