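"""Gene-level causation classifier.

A gene is *disease-causing* when it harbours at least one high-confidence
variant found in the Mendelian form of the disease — a very rare variant
(hspAF < 0.001) of the expected mechanism segregating in a hereditary
pedigree.  Genes whose pathologically relevant variants only raise risk are
*disease-predisposing*.  That census is the decisive (primary) criterion;
three further lines of evidence are recorded as supporting context:

* loss-of-function constraint (gnomAD o/e of pLoF variants): a low o/e
  supports a causing role for a LoF-mechanism gene; the score is meaningless
  for genes whose disease alleles are gain-of-function/proteotoxic and is
  marked inapplicable there;
* the aggregate odds ratio of the gene's pathologically relevant variants;
* the phenotype of naturally occurring human knockouts (severe early-onset
  disease vs mild/late or none).

Conflicts between the primary criterion and at least two secondary criteria
raise a warning flag on the decision but never overturn the census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .stats import or_supports_causing
from .types import (
    GeneEvidence,
    GeneRole,
    GeneRoleDecision,
    KnockoutPhenotype,
    Mechanism,
    OddsRatioEstimate,
    ValidationError,
    Verdict,
)

CRIT_MENDELIAN = "very_rare_mendelian_census"
CRIT_OE = "plof_constraint_oe"
CRIT_OR = "aggregate_odds_ratio"
CRIT_KNOCKOUT = "knockout_phenotype"


@dataclass(frozen=True)
class GeneRolePolicy:
    """Thresholds for the secondary gene-role criteria."""

    or_threshold: float = 10.0       # aggregate OR >= this supports causing
    oe_causing_max: float = 0.5      # o/e below this supports causing
    oe_predisposing_min: float = 1.0  # o/e above this supports predisposing

    def __post_init__(self) -> None:
        if not (0 < self.oe_causing_max <= self.oe_predisposing_min):
            raise ValidationError("o/e thresholds must satisfy 0 < causing <= predisposing")
        if self.or_threshold <= 0:
            raise ValidationError("OR threshold must be positive")


def _is_all_unknown(ev: GeneEvidence) -> bool:
    return (ev.n_very_rare_mendelian_variants is None
            and ev.oe_plof is None
            and ev.aggregate_or is None
            and ev.knockout_phenotype is KnockoutPhenotype.UNKNOWN)


def classify_gene_role(
    ev: GeneEvidence, policy: GeneRolePolicy = GeneRolePolicy()
) -> GeneRoleDecision:
    """Assign a causing/predisposing role from aggregated gene evidence."""
    lines: List[Tuple[str, Verdict, str]] = []

    if _is_all_unknown(ev):
        lines.append((CRIT_MENDELIAN, Verdict.NEUTRAL, "no evidence available"))
        return GeneRoleDecision(gene=ev.gene, role=GeneRole.UNASSIGNED,
                                evidence_lines=tuple(lines))

    # Primary criterion: census of very rare Mendelian-pedigree variants.
    n = ev.n_very_rare_mendelian_variants
    if n is None:
        primary = Verdict.NEUTRAL
        note = "Mendelian-pedigree variant census unknown"
    elif n >= 1:
        primary = Verdict.SUPPORTS_CAUSING
        note = f"{n} very rare variant(s) in Mendelian-form pedigrees"
    else:
        primary = Verdict.SUPPORTS_PREDISPOSING
        note = "no very rare variant reported from a Mendelian-form pedigree"
    lines.append((CRIT_MENDELIAN, primary, note))

    # Secondary: pLoF constraint, inapplicable for gain-type genes.
    if ev.primary_mechanism in (Mechanism.GOF, Mechanism.GOP):
        lines.append((CRIT_OE, Verdict.INAPPLICABLE,
                      "o/e uninformative: disease alleles are gain-type, and "
                      "LoF alleles of this gene are not the disease alleles"))
    elif ev.oe_plof is None:
        lines.append((CRIT_OE, Verdict.NEUTRAL, "o/e unknown"))
    elif ev.oe_plof < policy.oe_causing_max:
        lines.append((CRIT_OE, Verdict.SUPPORTS_CAUSING,
                      f"o/e {ev.oe_plof:g} < {policy.oe_causing_max:g} "
                      "indicates strong LoF intolerance"))
    elif ev.oe_plof > policy.oe_predisposing_min:
        lines.append((CRIT_OE, Verdict.SUPPORTS_PREDISPOSING,
                      f"o/e {ev.oe_plof:g} > {policy.oe_predisposing_min:g} "
                      "indicates no LoF intolerance"))
    else:
        lines.append((CRIT_OE, Verdict.NEUTRAL, f"o/e {ev.oe_plof:g} intermediate"))

    # Secondary: aggregate odds ratio.
    if ev.aggregate_or is None:
        lines.append((CRIT_OR, Verdict.NEUTRAL, "aggregate OR unknown"))
    else:
        lo, hi = ev.aggregate_or_ci
        est = OddsRatioEstimate(
            or_point=ev.aggregate_or,
            ci_low=lo if lo is not None else ev.aggregate_or,
            ci_high=hi if hi is not None else ev.aggregate_or)
        verdict, _ = or_supports_causing(est, policy.or_threshold)
        lines.append((CRIT_OR, verdict,
                      f"aggregate OR {ev.aggregate_or:g} vs threshold "
                      f"{policy.or_threshold:g}"))

    # Secondary: human knockout phenotype.
    ko = ev.knockout_phenotype
    if ko is KnockoutPhenotype.SEVERE_EARLY:
        lines.append((CRIT_KNOCKOUT, Verdict.SUPPORTS_CAUSING,
                      "human knockout shows severe early-onset disease"))
    elif ko is KnockoutPhenotype.MILD_LATE:
        lines.append((CRIT_KNOCKOUT, Verdict.SUPPORTS_PREDISPOSING,
                      "human knockout clinically mild / late-onset"))
    elif ko is KnockoutPhenotype.NONE_OBSERVED:
        lines.append((CRIT_KNOCKOUT, Verdict.SUPPORTS_PREDISPOSING,
                      "human knockout without disease phenotype"))
    else:
        lines.append((CRIT_KNOCKOUT, Verdict.NEUTRAL, "no human knockout reported"))

    # The census decides; a role is only withheld when it is unknown and no
    # pathologically relevant variants exist at all.
    if primary is Verdict.SUPPORTS_CAUSING:
        role = GeneRole.CAUSING
    elif ev.has_pathologically_relevant_variants:
        role = GeneRole.PREDISPOSING
    else:
        return GeneRoleDecision(gene=ev.gene, role=GeneRole.UNASSIGNED,
                                evidence_lines=tuple(lines))

    opposing = Verdict.SUPPORTS_PREDISPOSING if role is GeneRole.CAUSING \
        else Verdict.SUPPORTS_CAUSING
    n_conflicts = sum(1 for cid, v, _ in lines
                      if cid != CRIT_MENDELIAN and v is opposing)
    return GeneRoleDecision(
        gene=ev.gene,
        role=role,
        evidence_lines=tuple(lines),
        decisive_criterion=CRIT_MENDELIAN,
        conflict_warning=n_conflicts >= 2,
    )


def explain_decision(decision: GeneRoleDecision) -> str:
    """Deterministic human-readable rendering of a role decision."""
    if decision.role is GeneRole.UNASSIGNED:
        return f"{decision.gene}: unassigned — insufficient evidence"
    out = [f"{decision.gene}: {decision.role.value} "
           f"(decisive criterion: {decision.decisive_criterion})"]
    for cid, verdict, note in decision.evidence_lines:
        out.append(f"  [{cid}] {verdict.value}: {note}")
    if decision.conflict_warning:
        out.append("  warning: two or more secondary criteria oppose the "
                   "primary census criterion")
    return "\n".join(out)
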