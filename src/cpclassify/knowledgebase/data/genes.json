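{
  "evidence": {
    "PRSS1": {
      "n_very_rare_mendelian_variants": 12,
      "largest_pedigree": {"n_affected": 20, "n_generations": 4,
                           "relationship_note": "HCP families often have >=4 patients across >=3 generations"},
      "oe_plof": 1.31, "oe_ci": [0.86, 1.86],
      "aggregate_or": null, "aggregate_or_ci": [null, null],
      "knockout_phenotype": "unknown",
      "primary_mechanism": "GoF",
      "has_pathologically_relevant_variants": true,
      "context_note": "LoF alleles of this gene are protective, so pLoF constraint is uninformative"
    },
    "CFTR": {
      "n_very_rare_mendelian_variants": 0,
      "largest_pedigree": null,
      "oe_plof": 1.09, "oe_ci": [0.91, 1.31],
      "aggregate_or": 2.7, "aggregate_or_ci": [null, null],
      "knockout_phenotype": "unknown",
      "primary_mechanism": "LoF",
      "has_pathologically_relevant_variants": true,
      "context_note": "biallelic genotypes can cause cystic fibrosis; role here is CP-specific"
    },
    "SPINK1": {
      "n_very_rare_mendelian_variants": 3,
      "largest_pedigree": {"n_affected": 3, "n_generations": 3,
                           "relationship_note": "HCP families have at most 3 patients over 3 generations"},
      "oe_plof": 0.24, "oe_ci": [0.09, 1.13],
      "aggregate_or": 15.6, "aggregate_or_ci": [null, null],
      "knockout_phenotype": "severe_early",
      "primary_mechanism": "LoF",
      "has_pathologically_relevant_variants": true,
      "context_note": "human knockouts present severe exocrine pancreatic insufficiency in infancy"
    },
    "CTRC": {
      "n_very_rare_mendelian_variants": 0,
      "largest_pedigree": null,
      "oe_plof": 1.15, "oe_ci": [0.78, 1.69],
      "aggregate_or": 5.3, "aggregate_or_ci": [null, null],
      "knockout_phenotype": "mild_late",
      "primary_mechanism": "LoF",
      "has_pathologically_relevant_variants": true,
      "context_note": "human whole-locus knockout clinically asymptomatic until adulthood"
    }
  },
  "configs": {
    "PRSS1": {
      "mrna_accession": "NM_002769.5",
      "role": "causing",
      "af_threshold": 0.001,
      "pathogenic_min_loss": 0.95,
      "predisposing_min_loss": 0.10,
      "qualifying_mechanisms_for_pathogenic": ["GoF", "GoP"]
    },
    "SPINK1": {
      "mrna_accession": "NM_001379610.1",
      "role": "causing",
      "af_threshold": 0.001,
      "pathogenic_min_loss": 0.95,
      "predisposing_min_loss": 0.10,
      "qualifying_mechanisms_for_pathogenic": ["LoF"]
    },
    "CFTR": {
      "mrna_accession": "NM_000492.4",
      "role": "predisposing",
      "af_threshold": 0.001,
      "pathogenic_min_loss": 0.95,
      "predisposing_min_loss": 0.10,
      "qualifying_mechanisms_for_pathogenic": ["LoF"]
    },
    "CTRC": {
      "mrna_accession": "NM_007272.3",
      "role": "predisposing",
      "af_threshold": 0.001,
      "pathogenic_min_loss": 0.95,
      "predisposing_min_loss": 0.10,
      "qualifying_mechanisms_for_pathogenic": ["LoF"]
    }
  }
}
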