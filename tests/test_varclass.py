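"""The variant rule engine: published worked classifications, boundary
semantics, orientation flips and annotation strings."""

import dataclasses

import pytest

from cpclassify.knowledgebase import load_bundled_tables
from cpclassify.types import (
    ABSENT,
    Category,
    ClassificationSystem,
    EvidenceLevel,
    FunctionalEvidence,
    GeneConfig,
    GeneRole,
    LegacyCategory,
    Mechanism,
    PopulationFrequencySet,
    ValidationError,
    VariantRecord,
)
from cpclassify.varclass import (
    UnassignedGeneRoleError,
    UnsupportedSiteError,
    build_annotation,
    classify_variant,
    flip_risk_orientation,
    remap_legacy,
)

LOF_GENE = GeneConfig(gene="LOFG", role=GeneRole.CAUSING,
                      qualifying_mechanisms_for_pathogenic=frozenset(
                          {Mechanism.LOF}))
GOF_GENE = GeneConfig(gene="GOFG", role=GeneRole.CAUSING,
                      qualifying_mechanisms_for_pathogenic=frozenset(
                          {Mechanism.GOF, Mechanism.GOP}))
RISK_GENE = GeneConfig(gene="RISKG", role=GeneRole.PREDISPOSING)


def _variant(gene="LOFG", cdna="c.1A>G", hspaf=None, subpop="NFE",
             functional=FunctionalEvidence(), relevant=True, legacy=None,
             absent=False, **kwargs):
    subpops = {}
    if hspaf is not None:
        subpops[subpop] = hspaf
    freqs = PopulationFrequencySet(
        f"{gene}:{cdna}",
        global_af=ABSENT if absent else None,
        subpop_afs=subpops)
    return VariantRecord(gene=gene, cdna_hgvs=cdna, frequencies=freqs,
                         functional=functional, legacy_category=legacy,
                         pathologically_relevant=relevant, **kwargs)


class TestPublishedReclassifications:
    """The ten named worked reclassifications in PRSS1 and SPINK1."""

    EXPECTED = {
        "PRSS1:c.623G>C": Category.PREDISPOSING,      # p.Gly208Ala, hspAF ~0.01
        "PRSS1:c.276G>T": Category.LIKELY_PATHOGENIC,  # p.Lys92Asn
        "PRSS1:c.372C>T": Category.LIKELY_PATHOGENIC,  # p.Ser124Ser
        "PRSS1:c.111C>A": Category.BENIGN,             # p.Tyr37Ter, protective
        "PRSS1:c.200+1G>A": Category.BENIGN,           # protective pLoF
        "SPINK1:c.194+2T>C": Category.PREDISPOSING,    # ~90% loss, hspAF 0.003
        "SPINK1:c.101A>G": Category.BENIGN,            # p.Asn34Ser
        "SPINK1:c.-4141G>T": Category.PREDISPOSING,    # enhancer, hspAF 0.02
        "SPINK1:c.194G>A": Category.PREDISPOSING,      # p.Arg65Gln, ~50% loss
    }

    @pytest.mark.parametrize("key", sorted(EXPECTED))
    def test_reclassification_outcomes(self, key, reclassification_records,
                                       gene_configs):
        rec = reclassification_records[key]
        res = classify_variant(rec, gene_configs[rec.gene])
        assert res.category is self.EXPECTED[key]

    def test_protective_lof_flagged_and_qualified(self, reclassification_records,
                                                  gene_configs):
        rec = reclassification_records["PRSS1:c.200+1G>A"]
        res = classify_variant(rec, gene_configs["PRSS1"])
        assert "protective" in res.flags
        assert build_annotation(res, rec) == (
            "Benign (a loss-of-function mutation that was found in normal "
            "controls; protective against CP)")

    def test_promoter_risk_orientation_flip(self, reclassification_records,
                                            gene_configs):
        protective = reclassification_records["PRSS1:c.-204C>A"]
        risk = flip_risk_orientation(protective)
        assert risk.cdna_hgvs == "c.-204A>C"
        res = classify_variant(risk, gene_configs["PRSS1"])
        assert res.category is Category.PREDISPOSING
        assert "risk_orientation_flipped" in res.flags
        assert "odds ratio for ICP, 1.28" in build_annotation(res, risk)

    def test_cftr_phe508del_predisposing_with_cf_qualifier(
            self, reclassification_records, gene_configs):
        rec = reclassification_records["CFTR:c.1521_1523del"]
        res = classify_variant(rec, gene_configs["CFTR"])
        assert res.category is Category.PREDISPOSING
        assert res.system is ClassificationSystem.FIVE_CATEGORY
        assert res.qualifiers[0] == "cystic fibrosis-causing, severe"


class TestPathogenicAssignments:
    def test_prss1_arg122his_is_pathogenic(self, gene_configs):
        rec = next(r for r in load_bundled_tables("T2")
                   if r.cdna_hgvs == "c.365G>A")
        res = classify_variant(rec, gene_configs["PRSS1"])
        assert res.category is Category.PATHOGENIC

    def test_spink1_c27delc_is_pathogenic(self, gene_configs):
        rec = next(r for r in load_bundled_tables("T5")
                   if r.cdna_hgvs == "c.27delC")
        res = classify_variant(rec, gene_configs["SPINK1"])
        assert res.category is Category.PATHOGENIC


class TestRuleLadderSemantics:
    def test_unassigned_gene_role_is_an_error(self):
        cfg = GeneConfig(gene="LOFG", role=GeneRole.UNASSIGNED)
        with pytest.raises(UnassignedGeneRoleError):
            classify_variant(_variant(), cfg)

    def test_gene_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_variant(_variant(gene="GOFG"), LOF_GENE)

    def test_missing_frequency_data_degrades_to_vus_with_trace(self):
        fn = FunctionalEvidence(Mechanism.LOF, 1.0, EvidenceLevel.EXPERIMENTAL)
        res = classify_variant(_variant(functional=fn), LOF_GENE)
        assert res.category is Category.VUS
        assert any(t.rule_id == "7C-freq-missing" for t in res.traces)

    def test_observed_absent_counts_as_very_rare_not_missing(self):
        fn = FunctionalEvidence(Mechanism.LOF, 1.0, EvidenceLevel.EXPERIMENTAL)
        res = classify_variant(_variant(functional=fn, absent=True), LOF_GENE)
        assert res.category is Category.PATHOGENIC

    def test_loss_band_boundaries_are_open(self):
        # exactly 10% loss does not reach the predisposing band
        fn = FunctionalEvidence(Mechanism.LOF, 0.10, EvidenceLevel.EXPERIMENTAL)
        res = classify_variant(_variant(functional=fn, absent=True), LOF_GENE)
        assert res.category is not Category.PREDISPOSING
        # 95% loss reaches the pathogenic bar (inclusive)
        fn = FunctionalEvidence(Mechanism.LOF, 0.95, EvidenceLevel.EXPERIMENTAL)
        res = classify_variant(_variant(functional=fn, absent=True), LOF_GENE)
        assert res.category is Category.PATHOGENIC

    def test_af_threshold_boundary_is_strict(self):
        fn = FunctionalEvidence(Mechanism.LOF, 1.0, EvidenceLevel.EXPERIMENTAL)
        at = classify_variant(_variant(hspaf=0.001, functional=fn), LOF_GENE)
        below = classify_variant(_variant(hspaf=0.000999, functional=fn),
                                 LOF_GENE)
        assert at.category is Category.PREDISPOSING
        assert below.category is Category.PATHOGENIC

    def test_fired_rules_recorded_in_evaluation_order(self):
        fn = FunctionalEvidence(Mechanism.LOF, 0.5, EvidenceLevel.EXPERIMENTAL)
        res = classify_variant(_variant(functional=fn, absent=True), LOF_GENE)
        assert res.fired_rules[0] == "role-check"
        assert res.fired_rules[-1] == "7C-4-predisposing"


class TestMonotonicity:
    HSPAF_GRID = [1e-6, 1e-4, 9e-4, 1.1e-3, 0.01, 0.1]
    LOSS_GRID = [0.05, 0.2, 0.5, 0.94, 0.951, 1.0]

    def test_increasing_hspaf_only_moves_pathogenic_to_predisposing(self):
        fn = FunctionalEvidence(Mechanism.LOF, 1.0, EvidenceLevel.EXPERIMENTAL)
        severity = [classify_variant(_variant(hspaf=af, functional=fn),
                                     LOF_GENE).category
                    for af in self.HSPAF_GRID]
        rank = {Category.PATHOGENIC: 0, Category.PREDISPOSING: 1}
        ranks = [rank[c] for c in severity]
        assert ranks == sorted(ranks)

    def test_increasing_loss_only_moves_towards_pathogenic(self):
        rank = {Category.VUS: 0, Category.LIKELY_PREDISPOSING: 0,
                Category.PREDISPOSING: 1, Category.LIKELY_PATHOGENIC: 2,
                Category.PATHOGENIC: 3}
        ranks = []
        for loss in self.LOSS_GRID:
            fn = FunctionalEvidence(Mechanism.LOF, loss,
                                    EvidenceLevel.EXPERIMENTAL)
            ranks.append(rank[classify_variant(
                _variant(functional=fn, absent=True), LOF_GENE).category])
        assert ranks == sorted(ranks)


class TestFiveCategoryClosure:
    @pytest.mark.parametrize("legacy", list(LegacyCategory))
    def test_no_pathogenic_output_for_predisposing_genes(self, legacy):
        fn = FunctionalEvidence(Mechanism.LOF, 1.0, EvidenceLevel.EXPERIMENTAL)
        rec = _variant(gene="RISKG", functional=fn, legacy=legacy,
                       relevant=legacy in (LegacyCategory.PATHOGENIC,
                                           LegacyCategory.LIKELY_PATHOGENIC),
                       absent=True)
        res = classify_variant(rec, RISK_GENE)
        assert res.system is ClassificationSystem.FIVE_CATEGORY
        assert res.category not in (Category.PATHOGENIC,
                                    Category.LIKELY_PATHOGENIC)

    def test_legacy_likely_pathogenic_becomes_likely_predisposing(self):
        rec = _variant(gene="RISKG", legacy=LegacyCategory.LIKELY_PATHOGENIC,
                       relevant=True, absent=True)
        res = classify_variant(rec, RISK_GENE)
        assert res.category is Category.LIKELY_PREDISPOSING


class TestRemapLegacy:
    @pytest.mark.parametrize("legacy, expected", [
        (LegacyCategory.PATHOGENIC, Category.PREDISPOSING),
        (LegacyCategory.LIKELY_PATHOGENIC, Category.LIKELY_PREDISPOSING),
        (LegacyCategory.VUS, Category.VUS),
        (LegacyCategory.BENIGN, Category.BENIGN),
    ])
    def test_predisposing_gene_mapping(self, legacy, expected):
        assert remap_legacy(legacy, GeneRole.PREDISPOSING) is expected

    def test_causing_gene_mapping_is_identity(self):
        assert remap_legacy(LegacyCategory.PATHOGENIC, GeneRole.CAUSING) is \
            Category.PATHOGENIC

    @pytest.mark.parametrize("role", [GeneRole.PREDISPOSING, GeneRole.CAUSING])
    @pytest.mark.parametrize("legacy", list(LegacyCategory))
    def test_idempotence(self, legacy, role):
        once = remap_legacy(legacy, role)
        assert remap_legacy(once, role) is once


class TestRiskOrientationFlip:
    def test_flip_swaps_alleles_and_complements_frequencies(self):
        rec = _variant(gene="GOFG", cdna="c.-10C>A",
                       hspaf=0.3,
                       functional=FunctionalEvidence(
                           Mechanism.PROTECTIVE_LOF, None,
                           EvidenceLevel.EXPERIMENTAL))
        flipped = flip_risk_orientation(rec)
        assert flipped.cdna_hgvs == "c.-10A>C"
        assert flipped.frequencies.subpop_afs["NFE"] == pytest.approx(0.7)
        assert flipped.risk_orientation_flipped
        assert flipped.functional.mechanism is Mechanism.GOF

    def test_flip_is_an_involution(self):
        rec = _variant(gene="GOFG", cdna="c.-10C>A", hspaf=0.3,
                       functional=FunctionalEvidence(
                           Mechanism.PROTECTIVE_LOF, None,
                           EvidenceLevel.EXPERIMENTAL))
        assert flip_risk_orientation(flip_risk_orientation(rec)) == rec

    def test_non_substitution_site_unsupported(self):
        rec = _variant(gene="GOFG", cdna="c.1_3del", hspaf=0.3,
                       functional=FunctionalEvidence(
                           Mechanism.PROTECTIVE_LOF, None,
                           EvidenceLevel.EXPERIMENTAL))
        with pytest.raises(UnsupportedSiteError):
            flip_risk_orientation(rec)

    def test_non_protective_allele_rejected(self):
        with pytest.raises(ValidationError):
            flip_risk_orientation(_variant(hspaf=0.3))

    def test_absent_frequency_cannot_be_complemented(self):
        rec = _variant(gene="GOFG", cdna="c.-10C>A", absent=True,
                       functional=FunctionalEvidence(
                           Mechanism.PROTECTIVE_LOF, None,
                           EvidenceLevel.EXPERIMENTAL))
        with pytest.raises(ValidationError):
            flip_risk_orientation(rec)


class TestAnnotationStrings:
    def test_table_of_examples_round_trips_through_the_engine(
            self, reclassification_records, gene_configs):
        """The published qualifier examples assemble from classified records."""
        rec = reclassification_records["PRSS1:c.623G>C"]
        res = classify_variant(rec, gene_configs["PRSS1"])
        text = build_annotation(res, rec)
        assert text.startswith("Predisposing (Asian population-specific variant")
        assert "odds ratio for ICP, 4.92" in text
        assert text.endswith("a moderate effect on secretion)")

    def test_empty_qualifier_list_yields_bare_category(self):
        res = classify_variant(_variant(relevant=False, hspaf=1e-5), LOF_GENE)
        assert build_annotation(res) == "VUS"

    def test_annotation_is_deterministic(self, reclassification_records,
                                         gene_configs):
        rec = reclassification_records["SPINK1:c.194+2T>C"]
        res = classify_variant(rec, gene_configs["SPINK1"])
        assert build_annotation(res, rec) == build_annotation(res, rec)
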