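"""Allele-frequency mathematics: hspAF, the very-rare predicate, carrier
arithmetic and the gold-standard audit."""

import pytest
from hypothesis import given, settings, strategies as st

from cpclassify.popfreq import (
    CarrierMode,
    audit_gold_standard,
    carrier_frequency,
    highest_subpop_af,
    is_very_rare,
    prevalence_ratio,
)
from cpclassify.types import (
    ABSENT,
    PopulationFrequencySet,
    SUBPOPULATIONS,
    ValidationError,
    VariantRecord,
    _Absent,
)


def _freqs(subpops, global_af=None):
    return PopulationFrequencySet("k", global_af=global_af, subpop_afs=subpops)


class TestHighestSubpopAf:
    def test_returns_maximum_with_its_subpopulation(self):
        code, af = highest_subpop_af(_freqs({"EAS": 0.0007018, "NFE": 0.00001}))
        assert (code, af) == ("EAS", 0.0007018)

    def test_all_absent_reports_absent(self):
        assert highest_subpop_af(
            _freqs({c: ABSENT for c in SUBPOPULATIONS})) is ABSENT

    def test_global_frequency_never_consulted(self):
        assert highest_subpop_af(_freqs({}, global_af=0.5)) is ABSENT

    @settings(derandomize=True, max_examples=200)
    @given(st.dictionaries(
        st.sampled_from(SUBPOPULATIONS),
        st.one_of(st.just(ABSENT),
                  st.floats(min_value=0, max_value=1, allow_nan=False)),
        max_size=8))
    def test_matches_brute_force_scan(self, subpops):
        result = highest_subpop_af(_freqs(subpops))
        numeric = {c: v for c, v in subpops.items()
                   if not isinstance(v, _Absent)}
        if not numeric:
            assert result is ABSENT
        else:
            code, af = result
            assert af == max(numeric.values())
            assert numeric[code] == af


class TestVeryRare:
    @pytest.mark.parametrize("subpops, expected", [
        ({"EAS": 0.0007018}, True),     # below threshold in every subpopulation
        ({"AFR": 0.03078}, False),      # common in one subpopulation
        ({"NFE": 0.001}, False),        # strict inequality at the boundary
        ({c: ABSENT for c in SUBPOPULATIONS}, True),  # fully absent
    ])
    def test_threshold_semantics(self, subpops, expected):
        assert is_very_rare(_freqs(subpops)) is expected

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0, max_value=1, allow_nan=False),
           st.floats(min_value=0, max_value=1, allow_nan=False))
    def test_monotone_nonincreasing_in_hspaf(self, a, b):
        lo, hi = sorted((a, b))
        rare_hi = is_very_rare(_freqs({"NFE": hi}))
        rare_lo = is_very_rare(_freqs({"NFE": lo}))
        assert rare_lo or not rare_hi


class TestCarrierArithmetic:
    def test_bound_2p_gives_the_dominant_filter_value(self):
        assert carrier_frequency(0.001, CarrierMode.BOUND_2P) == 0.002

    def test_hardy_weinberg_exact_value(self):
        assert carrier_frequency(0.001, CarrierMode.HARDY_WEINBERG) == \
            pytest.approx(0.001998)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0, max_value=1, allow_nan=False))
    def test_bound_dominates_hardy_weinberg(self, p):
        assert carrier_frequency(p, CarrierMode.BOUND_2P) >= \
            carrier_frequency(p, CarrierMode.HARDY_WEINBERG)

    def test_zero_frequency_means_no_carriers(self):
        assert carrier_frequency(0.0) == 0.0
        assert carrier_frequency(0.0, CarrierMode.HARDY_WEINBERG) == 0.0

    def test_prevalence_ratio_against_direct_quotient(self):
        # 2 * 0.001 / 3e-6 = 666.67 to 2 dp — comfortably above 600
        ratio = prevalence_ratio(0.001, 0.3 / 100_000)
        assert ratio == pytest.approx(666.6667, abs=0.01)
        assert ratio > 600

    def test_prevalence_ratio_is_linear_in_threshold(self):
        assert prevalence_ratio(0.0005, 3e-6) == \
            pytest.approx(prevalence_ratio(0.001, 3e-6) / 2)

    def test_ratio_of_equal_quantities_is_one(self):
        assert prevalence_ratio(0.01, 0.02) == pytest.approx(1.0)

    @pytest.mark.parametrize("call", [
        lambda: carrier_frequency(1.2),
        lambda: prevalence_ratio(0.001, 0.0),
        lambda: prevalence_ratio(0.001, -1e-6),
    ])
    def test_domain_errors(self, call):
        with pytest.raises(ValidationError):
            call()


def _gold(key, subpops=None, global_af=None):
    return VariantRecord(
        gene="G", cdna_hgvs=key, structural=True,
        frequencies=_freqs(subpops or {}, global_af=global_af),
        pathologically_relevant=True, gold_standard=True)


class TestGoldStandardAudit:
    def test_bundled_gold_standard_census(self, gold_standard_records):
        audit = audit_gold_standard(gold_standard_records)
        assert audit.n_total == 47
        assert audit.n_present_in_population == 9
        assert round(audit.fraction_present, 2) == 0.19
        assert audit.outliers == (("SPINK1:c.200G>A", 0.03078),)
        assert audit.max_hspaf == pytest.approx(0.0007018)
        assert audit.max_hspaf_variant == "PRSS1:c.346C>T"

    def test_all_absent_input_counts_nothing_present(self):
        audit = audit_gold_standard(
            [_gold(f"v{i}", global_af=ABSENT) for i in range(5)])
        assert audit.n_present_in_population == 0
        assert audit.outliers == ()
        assert audit.max_hspaf is None

    def test_presence_conservation(self, gold_standard_records):
        audit = audit_gold_standard(gold_standard_records)
        absent = sum(1 for r in gold_standard_records
                     if not r.frequencies.present_subpops()
                     and isinstance(r.frequencies.global_af, _Absent))
        assert audit.n_present_in_population + absent == audit.n_total

    def test_raising_threshold_never_adds_outliers(self, gold_standard_records):
        lo = audit_gold_standard(gold_standard_records, threshold=0.0001)
        hi = audit_gold_standard(gold_standard_records, threshold=0.01)
        assert set(hi.outliers) <= set(lo.outliers)

    def test_empty_input_is_a_domain_error(self):
        with pytest.raises(ValidationError):
            audit_gold_standard([])

    def test_non_gold_records_rejected(self, reclassification_records):
        with pytest.raises(ValidationError):
            audit_gold_standard(
                [reclassification_records["PRSS1:c.623G>C"]])
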