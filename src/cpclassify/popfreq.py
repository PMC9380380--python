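"""Allele-frequency mathematics.

The framework's frequency filter works on the *highest subpopulation allele
frequency* (hspAF), not the global frequency: an allele common in one ancestry
group is not rare, however diluted it looks globally.  A variant is "very
rare" when its hspAF is strictly below the threshold (default 0.001) in every
subpopulation; a variant absent from the reference population altogether is
very rare by definition.

The module also provides the carrier-frequency / disease-prevalence arithmetic
used to justify the 0.001 threshold for a dominant disease, and the audit of a
gold-standard calibration set: how many maximal-confidence pathogenic variants
are seen in population data at all, which ones exceed the threshold (outliers),
and what the highest hspAF is once outliers are excluded.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Sequence, Tuple, Union

from .types import (
    ABSENT,
    GoldStandardAudit,
    PopulationFrequencySet,
    ValidationError,
    VariantRecord,
    _Absent,
)


class CarrierMode(str, enum.Enum):
    BOUND_2P = "bound_2p"               # carrier frequency <= 2p (upper bound)
    HARDY_WEINBERG = "hardy_weinberg"   # exact 2p(1-p) under HWE


def highest_subpop_af(
    freqs: PopulationFrequencySet,
) -> Union[Tuple[str, float], _Absent]:
    """Return ``(subpopulation, frequency)`` for the highest subpopulation
    allele frequency, or :data:`ABSENT` when no subpopulation has a numeric
    frequency.  The global frequency is never consulted."""
    present = freqs.present_subpops()
    if not present:
        return ABSENT
    code = max(sorted(present), key=lambda c: present[c])
    return code, present[code]


def _hspaf_value(freqs: PopulationFrequencySet) -> Optional[float]:
    hs = highest_subpop_af(freqs)
    if isinstance(hs, _Absent):
        return None
    return hs[1]


def is_very_rare(freqs: PopulationFrequencySet, threshold: float = 0.001) -> bool:
    """True iff the variant's hspAF is strictly below ``threshold``.

    A fully absent frequency set counts as very rare.  The boundary is strict:
    hspAF exactly equal to the threshold is *not* very rare.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    hspaf = _hspaf_value(freqs)
    if hspaf is None:
        return True
    return hspaf < threshold


def carrier_frequency(af: float, mode: CarrierMode = CarrierMode.BOUND_2P) -> float:
    """Heterozygous-carrier frequency for allele frequency ``af``.

    ``bound_2p`` gives the conservative upper bound 2p used in dominant-disease
    filtering arithmetic; ``hardy_weinberg`` gives the exact 2p(1-p).
    """
    if not (0.0 <= af <= 1.0):
        raise ValidationError(f"allele frequency must lie in [0, 1], got {af}")
    mode = CarrierMode(mode)
    if mode is CarrierMode.BOUND_2P:
        return 2.0 * af
    return 2.0 * af * (1.0 - af)


def prevalence_ratio(
    af_threshold: float,
    prevalence: float,
    mode: CarrierMode = CarrierMode.BOUND_2P,
) -> float:
    """Ratio of the carrier frequency at ``af_threshold`` to the disease
    prevalence (per individual).

    A large ratio means the frequency cutoff is very conservative for a
    dominant disease: far more carriers would exist than there are patients.
    """
    if prevalence <= 0:
        raise ValidationError("prevalence must be positive")
    return carrier_frequency(af_threshold, mode) / prevalence


def audit_gold_standard(
    variants: Sequence[VariantRecord],
    threshold: float = 0.001,
) -> GoldStandardAudit:
    """Audit a gold-standard variant set against population frequency data.

    Counts how many records have any numeric population frequency, flags as
    outliers those whose hspAF reaches the threshold, and reports the maximum
    hspAF among the remaining (non-outlier) records.
    """
    records = list(variants)
    if not records:
        raise ValidationError("cannot audit an empty gold-standard set")
    for rec in records:
        if not rec.gold_standard:
            raise ValidationError(f"{rec.key} is not flagged gold_standard")

    n_present = 0
    outliers: list[Tuple[str, float]] = []
    best_key: Optional[str] = None
    best_af: Optional[float] = None
    for rec in records:
        fr = rec.frequencies
        numeric_global = fr.global_af is not None and not isinstance(fr.global_af, _Absent)
        hspaf = _hspaf_value(fr)
        if numeric_global or hspaf is not None:
            n_present += 1
        if hspaf is None:
            continue
        if hspaf >= threshold:
            outliers.append((rec.key, hspaf))
        elif best_af is None or hspaf > best_af:
            best_key, best_af = rec.key, hspaf
    return GoldStandardAudit(
        n_total=len(records),
        n_present_in_population=n_present,
        max_hspaf_variant=best_key,
        max_hspaf=best_af,
        outliers=tuple(outliers),
        threshold_used=threshold,
    )
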