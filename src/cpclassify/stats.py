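"""Odds-ratio arithmetic for the framework's effect-size criteria.

Aggregate odds ratios are one of the converging lines of evidence separating
disease-causing from disease-predisposing genes: variants in a causing gene
carry a large genetic effect (e.g. an aggregate OR of 15.6 for *SPINK1*),
whereas even complete loss-of-function alleles of a predisposing gene confer
modest risk (*CFTR* 2.7, *CTRC* 5.3).

The interval is the standard Woolf log-OR interval,

    OR = ad / bc,     CI = exp( ln OR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ),

with the Haldane-Anscombe +0.5 continuity correction applied to every cell
whenever any cell is zero (flagged in the output).
"""

from __future__ import annotations

import math

from scipy.stats import norm

from .types import (
    ContingencyTable2x2,
    OddsRatioEstimate,
    ValidationError,
    Verdict,
)


class UndefinedOddsRatioError(ValidationError):
    """The odds ratio is undefined (a whole row or column is empty)."""


def odds_ratio_ci(t: ContingencyTable2x2, alpha: float = 0.05) -> OddsRatioEstimate:
    """Woolf odds ratio with a (1-alpha) log-normal confidence interval."""
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    a, b = t.case_carrier, t.case_noncarrier
    c, d = t.control_carrier, t.control_noncarrier
    # A doubly-empty margin leaves the OR undefined even after correction.
    if (a == 0 and b == 0) or (c == 0 and d == 0) \
            or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise UndefinedOddsRatioError(
            f"odds ratio undefined for table ({a}, {b}, {c}, {d})")
    correction = any(x == 0 for x in (a, b, c, d))
    if correction:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(1 - alpha / 2))
    log_or = math.log(or_point)
    return OddsRatioEstimate(
        or_point=or_point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        correction_applied=correction,
    )


def or_supports_causing(
    est: OddsRatioEstimate, threshold: float = 10.0
) -> tuple[Verdict, float]:
    """Verdict on the gene-role criterion "large aggregate genetic effect".

    Returns ``(verdict, margin)`` where the margin is the log-fold distance of
    the point estimate from the policy threshold (positive towards causing).
    ``or_point >= threshold`` supports a causing role.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    margin = math.log(est.or_point / threshold)
    verdict = (Verdict.SUPPORTS_CAUSING if est.or_point >= threshold
               else Verdict.SUPPORTS_PREDISPOSING)
    return verdict, margin
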