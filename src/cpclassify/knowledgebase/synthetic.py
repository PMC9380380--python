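"""Synthetic variant generator with known ground-truth categories.

Each synthetic record is built *inside* an unambiguous region of the rule
space for its target category — allele frequencies and loss fractions are
sampled at least ``EPSILON`` away from every decision boundary — so the rule
engine must recover the generator's category exactly.  Three synthetic gene
contexts are emulated:

* ``GOFG1`` — a causing gene whose disease alleles are gain-of-function /
  gain-of-proteotoxicity (a *PRSS1*-like context);
* ``LOFG1`` — a causing gene whose disease alleles are loss-of-function
  (a *SPINK1*-like context);
* ``RISKG1`` — a predisposing gene (a *CFTR*/*CTRC*-like context).

The generator emulates the study conditions of the bundled evidence tables:
very rare alleles are drawn log-uniformly below the 0.001 threshold (or are
absent from the reference population outright, as most gold-standard alleles
are), common risk alleles log-uniformly between the threshold and 0.1, and
loss fractions uniformly inside the relevant band.  It does not emulate
linkage between variants, per-subpopulation correlation structure, or
sampling noise on frequencies — frequencies are treated as known point
estimates, exactly as the classification framework itself treats them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

from ..types import (
    ABSENT,
    Category,
    EvidenceLevel,
    FunctionalEvidence,
    GeneConfig,
    GeneRole,
    LegacyCategory,
    Mechanism,
    PopulationFrequencySet,
    SUBPOPULATIONS,
    ValidationError,
    VariantRecord,
)

#: Minimum sampled distance from any decision boundary.
EPSILON = 1e-6


class ConfigurationError(ValidationError):
    """Degenerate generator parameters (e.g. a law straddling a threshold)."""


def _round6(x: float) -> float:
    """Round to the 6 significant digits the interchange format carries.

    The rounding step (at most one part in 1e5) is far smaller than the
    EPSILON margins kept from every threshold, so it never moves a sampled
    value across a boundary.
    """
    return float(f"{x:.6g}")


@dataclass(frozen=True)
class AfLaw:
    """Log-uniform allele-frequency law, split at the gene's AF threshold."""

    log10_min: float = -6.0
    log10_max: float = -1.0
    p_absent: float = 0.3  # probability that a very rare allele is absent

    def __post_init__(self) -> None:
        if not (self.log10_min < self.log10_max):
            raise ConfigurationError(
                "degenerate allele-frequency law: log10_min must be < log10_max")
        if not (0.0 <= self.p_absent <= 1.0):
            raise ConfigurationError("p_absent must lie in [0, 1]")


@dataclass(frozen=True)
class LossLaw:
    """Uniform loss-fraction law inside each classification band."""

    margin: float = 1e-4  # distance kept from the 0.10 / 0.95 boundaries

    def __post_init__(self) -> None:
        if not (EPSILON <= self.margin < 0.1):
            raise ConfigurationError(
                f"degenerate loss law: margin must lie in [{EPSILON}, 0.1)")


_DEFAULT_MIX: Dict[str, float] = {"gof_gene": 1 / 3, "lof_gene": 1 / 3,
                                  "predisposing_gene": 1 / 3}

_CAUSING_CATEGORIES = (
    Category.PATHOGENIC, Category.LIKELY_PATHOGENIC, Category.PREDISPOSING,
    Category.LIKELY_PREDISPOSING, Category.VUS, Category.LIKELY_BENIGN,
    Category.BENIGN)
_PREDISPOSING_CATEGORIES = (
    Category.PREDISPOSING, Category.LIKELY_PREDISPOSING, Category.VUS,
    Category.LIKELY_BENIGN, Category.BENIGN)


def synthetic_gene_configs() -> Dict[str, GeneConfig]:
    """The three synthetic gene contexts used by the generator."""
    return {
        "GOFG1": GeneConfig(
            gene="GOFG1", mrna_accession="NM_000001.1", role=GeneRole.CAUSING,
            qualifying_mechanisms_for_pathogenic=frozenset(
                {Mechanism.GOF, Mechanism.GOP})),
        "LOFG1": GeneConfig(
            gene="LOFG1", mrna_accession="NM_000002.1", role=GeneRole.CAUSING,
            qualifying_mechanisms_for_pathogenic=frozenset({Mechanism.LOF})),
        "RISKG1": GeneConfig(
            gene="RISKG1", mrna_accession="NM_000003.1",
            role=GeneRole.PREDISPOSING,
            qualifying_mechanisms_for_pathogenic=frozenset({Mechanism.LOF})),
    }


@dataclass(frozen=True)
class SyntheticVariant:
    """A generated record together with its hidden ground truth."""

    record: VariantRecord
    config: GeneConfig
    true_category: Category


def _rare_freqs(rng: np.random.Generator, cfg: GeneConfig, law: AfLaw,
                key: str) -> PopulationFrequencySet:
    """hspAF strictly below the threshold (or fully absent)."""
    if rng.random() < law.p_absent:
        return PopulationFrequencySet(
            variant_key=key, global_af=ABSENT,
            subpop_afs={code: ABSENT for code in SUBPOPULATIONS[:3]},
            source_note="synthetic")
    hi = math.log10(cfg.af_threshold * (1.0 - 1e-3))
    lo = min(law.log10_min, hi - 1.0)
    af = _round6(float(10 ** rng.uniform(lo, hi)))
    subpop = SUBPOPULATIONS[int(rng.integers(len(SUBPOPULATIONS)))]
    return PopulationFrequencySet(
        variant_key=key, global_af=_round6(af * 0.5),
        subpop_afs={subpop: af}, source_note="synthetic")


def _common_freqs(rng: np.random.Generator, cfg: GeneConfig, law: AfLaw,
                  key: str) -> PopulationFrequencySet:
    """hspAF strictly above the threshold."""
    lo = math.log10(cfg.af_threshold * (1.0 + 1e-3))
    hi = max(law.log10_max, lo + 0.5)
    af = _round6(min(float(10 ** rng.uniform(lo, hi)), 1.0))
    subpop = SUBPOPULATIONS[int(rng.integers(len(SUBPOPULATIONS)))]
    return PopulationFrequencySet(
        variant_key=key, global_af=_round6(af * 0.5),
        subpop_afs={subpop: af}, source_note="synthetic")


def _loss_in(rng: np.random.Generator, lo: float, hi: float) -> float:
    return _round6(float(rng.uniform(lo, hi)))


def _causing_recipe(rng: np.random.Generator, cfg: GeneConfig, gof: bool,
                    category: Category, af_law: AfLaw, loss_law: LossLaw,
                    key: str):
    """Build (freqs, functional, relevant, legacy) for a causing-gene truth."""
    m = loss_law.margin
    path_lo = cfg.pathogenic_min_loss + m
    band_lo, band_hi = cfg.predisposing_min_loss + m, cfg.pathogenic_min_loss - m
    rare = lambda: _rare_freqs(rng, cfg, af_law, key)
    common = lambda: _common_freqs(rng, cfg, af_law, key)

    if category is Category.PATHOGENIC:
        if gof:
            mech = Mechanism.GOF if rng.random() < 0.5 else Mechanism.GOP
            notes = ({"increased_activation"} if mech is Mechanism.GOF
                     else {"reduced_secretion", "er_stress_marker"})
            fn = FunctionalEvidence(mech, None, EvidenceLevel.EXPERIMENTAL,
                                    frozenset(notes))
        elif rng.random() < 0.5:
            fn = FunctionalEvidence(Mechanism.LOF, 1.0,
                                    EvidenceLevel.PRESUMED_COMPLETE)
        else:
            fn = FunctionalEvidence(Mechanism.LOF, _loss_in(rng, path_lo, 1.0),
                                    EvidenceLevel.EXPERIMENTAL)
        return rare(), fn, True, None
    if category is Category.LIKELY_PATHOGENIC:
        if gof:
            fn = FunctionalEvidence(
                Mechanism.GOP, None, EvidenceLevel.EXPERIMENTAL,
                frozenset({"secretion_moderate_impact", "er_stress_untested"}))
        else:
            fn = FunctionalEvidence(Mechanism.LOF, _loss_in(rng, path_lo, 1.0),
                                    EvidenceLevel.PREDICTED)
        return rare(), fn, True, None
    if category is Category.PREDISPOSING:
        if gof:
            fn = FunctionalEvidence(Mechanism.GOF, None,
                                    EvidenceLevel.EXPERIMENTAL,
                                    frozenset({"increased_activation"}))
            return common(), fn, True, None
        if rng.random() < 0.5:  # common allele with complete loss
            fn = FunctionalEvidence(Mechanism.LOF, _loss_in(rng, path_lo, 1.0),
                                    EvidenceLevel.EXPERIMENTAL)
            return common(), fn, True, None
        fn = FunctionalEvidence(Mechanism.LOF, _loss_in(rng, band_lo, band_hi),
                                EvidenceLevel.EXPERIMENTAL)
        return rare(), fn, True, None
    if category is Category.LIKELY_PREDISPOSING:
        mech = (Mechanism.GOF if gof else Mechanism.LOF)
        fn = FunctionalEvidence(mech, None, EvidenceLevel.PREDICTED)
        return rare(), fn, True, None
    if category is Category.VUS:
        fn = FunctionalEvidence(Mechanism.UNKNOWN, None, EvidenceLevel.NONE)
        return rare(), fn, False, None
    if category is Category.LIKELY_BENIGN:
        fn = FunctionalEvidence(Mechanism.NEUTRAL, None, EvidenceLevel.PREDICTED)
        return (rare() if rng.random() < 0.5 else common()), fn, False, None
    # benign: experimentally neutral or protective LoF
    if rng.random() < 0.5:
        fn = FunctionalEvidence(Mechanism.NEUTRAL, 0.0,
                                EvidenceLevel.EXPERIMENTAL)
    else:
        fn = FunctionalEvidence(Mechanism.PROTECTIVE_LOF, 1.0,
                                EvidenceLevel.EXPERIMENTAL)
    return (rare() if rng.random() < 0.5 else common()), fn, False, None


def _predisposing_recipe(rng: np.random.Generator, cfg: GeneConfig,
                         category: Category, af_law: AfLaw, key: str):
    rare = lambda: _rare_freqs(rng, cfg, af_law, key)
    common = lambda: _common_freqs(rng, cfg, af_law, key)
    freqs = rare() if rng.random() < 0.5 else common()
    if category is Category.PREDISPOSING:
        fn = FunctionalEvidence(Mechanism.LOF, 1.0, EvidenceLevel.EXPERIMENTAL)
        legacy = LegacyCategory.PATHOGENIC if rng.random() < 0.5 else None
        return freqs, fn, True, legacy
    if category is Category.LIKELY_PREDISPOSING:
        fn = FunctionalEvidence(Mechanism.LOF, None, EvidenceLevel.PREDICTED)
        return freqs, fn, True, LegacyCategory.LIKELY_PATHOGENIC
    if category is Category.VUS:
        fn = FunctionalEvidence(Mechanism.UNKNOWN, None, EvidenceLevel.NONE)
        return freqs, fn, False, None
    if category is Category.LIKELY_BENIGN:
        fn = FunctionalEvidence(Mechanism.NEUTRAL, None, EvidenceLevel.PREDICTED)
        return freqs, fn, False, None
    fn = FunctionalEvidence(Mechanism.NEUTRAL, 0.0, EvidenceLevel.EXPERIMENTAL)
    return freqs, fn, False, None


def generate_synthetic_variants(
    n: int,
    seed: int,
    af_law: Optional[AfLaw] = None,
    loss_law: Optional[LossLaw] = None,
    mechanism_mix: Optional[Mapping[str, float]] = None,
) -> List[SyntheticVariant]:
    """Generate ``n`` synthetic variants with hidden ground-truth categories.

    Deterministic given ``seed``.  ``mechanism_mix`` gives the proportions of
    the three gene contexts (keys ``gof_gene``, ``lof_gene``,
    ``predisposing_gene``) and must sum to 1.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    af_law = af_law or AfLaw()
    loss_law = loss_law or LossLaw()
    mix = dict(mechanism_mix) if mechanism_mix is not None else dict(_DEFAULT_MIX)
    if set(mix) != set(_DEFAULT_MIX):
        raise ConfigurationError(
            f"mechanism_mix keys must be {sorted(_DEFAULT_MIX)}")
    total = sum(mix.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ConfigurationError(f"mechanism_mix must sum to 1, got {total}")

    configs = synthetic_gene_configs()
    contexts = ("gof_gene", "lof_gene", "predisposing_gene")
    context_genes = {"gof_gene": "GOFG1", "lof_gene": "LOFG1",
                     "predisposing_gene": "RISKG1"}
    probs = np.array([mix[c] for c in contexts], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    out: List[SyntheticVariant] = []
    for i in range(n):
        context = contexts[int(rng.choice(len(contexts), p=probs))]
        gene = context_genes[context]
        cfg = configs[gene]
        cdna = f"c.{i + 1}A>G"
        key = f"{gene}:{cdna}"
        if context == "predisposing_gene":
            cats = _PREDISPOSING_CATEGORIES
            category = cats[int(rng.integers(len(cats)))]
            freqs, fn, relevant, legacy = _predisposing_recipe(
                rng, cfg, category, af_law, key)
        else:
            cats = _CAUSING_CATEGORIES
            category = cats[int(rng.integers(len(cats)))]
            freqs, fn, relevant, legacy = _causing_recipe(
                rng, cfg, context == "gof_gene", category, af_law, loss_law, key)
        record = VariantRecord(
            gene=gene, cdna_hgvs=cdna, frequencies=freqs, functional=fn,
            legacy_category=legacy, pathologically_relevant=relevant)
        out.append(SyntheticVariant(record=record, config=cfg,
                                    true_category=category))
    return out
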