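"""The variant rule engine.

Variants in a *predisposing* gene are classified on the five-category scale:
every pathologically relevant variant is "predisposing" (a legacy "likely
pathogenic" call becomes "likely predisposing"), and "pathogenic"/"likely
pathogenic" are never emitted.

Variants in a *causing* gene are classified on the seven-category scale by a
fixed, first-match-wins rule ladder:

1. ``7C-1-protective``       a protective loss-of-function allele is benign,
                             flagged and qualified as protective;
2. ``7C-2-pathogenic``       very rare (hspAF < threshold) AND full functional
                             qualification — for gain-type genes an
                             experimentally demonstrated qualifying GoF/GoP
                             effect with a complete assay panel; for LoF genes
                             a functional loss >= the pathogenic threshold
                             (default 0.95) demonstrated or presumed complete;
3. ``7C-3-likely-pathogenic`` very rare with partial functional support — an
                             experimental gain-type assay with an incomplete
                             panel (e.g. moderate secretion impact, ER stress
                             untested), or a predicted-only complete loss;
4. ``7C-4-predisposing``     pathologically relevant AND (hspAF >= threshold
                             OR functional loss inside the predisposing band,
                             default (0.10, 0.95));
5. ``7C-5-likely-predisposing`` pathologically relevant with suggestive,
                             non-experimental evidence only;
6. ``7C-6-residual``         remaining variants: experimentally neutral ->
                             benign, predicted neutral -> likely benign,
                             legacy benign-side call honoured, else VUS.

A variant that reaches a frequency rule with no frequency data at all (never
measured, as opposed to observed-absent) degrades to VUS with an explicit
"insufficient frequency data" trace.
"""

from __future__ import annotations

import re
from dataclasses import replace
from typing import List, Optional, Tuple

from .popfreq import highest_subpop_af, is_very_rare
from .types import (
    ABSENT,
    Category,
    ClassificationResult,
    ClassificationSystem,
    EvidenceLevel,
    FunctionalEvidence,
    GeneConfig,
    GeneRole,
    LegacyCategory,
    Mechanism,
    PopulationFrequencySet,
    RuleTrace,
    ValidationError,
    VariantRecord,
    _Absent,
)

PROTECTIVE_QUALIFIER = "protective against CP"

#: Assay flags that mark an experimental panel as incomplete.
_PARTIAL_PANEL_FLAGS = frozenset({"secretion_moderate_impact", "er_stress_untested"})

#: Published rule registry (evaluation order for causing genes).
RULE_REGISTRY: Tuple[str, ...] = (
    "role-check",
    "5C-relevant-predisposing",
    "5C-nonrelevant",
    "7C-1-protective",
    "7C-freq-missing",
    "7C-2-pathogenic",
    "7C-3-likely-pathogenic",
    "7C-4-predisposing",
    "7C-5-likely-predisposing",
    "7C-6-residual",
)


class UnassignedGeneRoleError(ValidationError):
    """The gene must be classified (causing vs predisposing) first."""


class UnsupportedSiteError(ValidationError):
    """Risk-orientation flips only apply to simple biallelic substitutions."""


def remap_legacy(category: LegacyCategory | Category, role: GeneRole) -> Category:
    """Translate a legacy five-tier category into the framework category.

    For predisposing genes, "pathogenic" maps to "predisposing" and "likely
    pathogenic" to "likely predisposing"; everything else is unchanged.  For
    causing genes the mapping is the identity (a fresh classification through
    :func:`classify_variant` is required instead).  Idempotent.
    """
    value = category.value if isinstance(category, (LegacyCategory, Category)) else str(category)
    if value == LegacyCategory.PROTECTIVE.value:
        return Category.BENIGN
    cat = Category(value)
    if role is GeneRole.PREDISPOSING:
        if cat is Category.PATHOGENIC:
            return Category.PREDISPOSING
        if cat is Category.LIKELY_PATHOGENIC:
            return Category.LIKELY_PREDISPOSING
    return cat


_SUBSTITUTION_RE = re.compile(
    r"^(?P<prefix>[cgmn]\.[-*+\d_]+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


def flip_risk_orientation(v: VariantRecord) -> VariantRecord:
    """Re-express a protective allele as its risk-allele counterpart.

    The reference and alternate bases are swapped in the HGVS string, every
    numeric allele frequency is complemented (af -> 1 - af), the protective
    loss-of-function mechanism becomes gain-of-function (reduced expression of
    a risk-promoting gene is protective; the opposite allele raises
    expression), and the ``risk_orientation_flipped`` flag is toggled.
    Flipping twice restores the original record.
    """
    if (v.functional.mechanism not in (Mechanism.PROTECTIVE_LOF, Mechanism.GOF)
            and v.legacy_category is not LegacyCategory.PROTECTIVE):
        raise ValidationError(
            f"{v.key} is not a protective (or previously flipped) allele")
    m = _SUBSTITUTION_RE.match(v.cdna_hgvs)
    if m is None:
        raise UnsupportedSiteError(
            f"risk-orientation flip needs a simple biallelic substitution, "
            f"got {v.cdna_hgvs!r}")
    flipped_hgvs = f"{m.group('prefix')}{m.group('alt')}>{m.group('ref')}"

    def _complement(af):
        if af is None:
            return None
        if isinstance(af, _Absent):
            raise ValidationError(
                f"cannot complement an observed-absent frequency for {v.key}")
        # round away binary representation drift so the flip is an involution
        return round(1.0 - af, 12)

    fr = v.frequencies
    new_freqs = PopulationFrequencySet(
        variant_key=f"{v.gene}:{flipped_hgvs}",
        global_af=_complement(fr.global_af),
        subpop_afs={c: _complement(af) for c, af in fr.subpop_afs.items()},
        source_note=fr.source_note,
        partitions_global=fr.partitions_global,
    )
    mech_swap = {Mechanism.PROTECTIVE_LOF: Mechanism.GOF,
                 Mechanism.GOF: Mechanism.PROTECTIVE_LOF}
    new_mech = mech_swap.get(v.functional.mechanism, v.functional.mechanism)
    new_functional = FunctionalEvidence(
        mechanism=new_mech,
        loss_fraction=None,
        evidence_level=v.functional.evidence_level,
        assay_notes=v.functional.assay_notes,
    )
    return replace(
        v,
        cdna_hgvs=flipped_hgvs,
        frequencies=new_freqs,
        functional=new_functional,
        risk_orientation_flipped=not v.risk_orientation_flipped,
    )


def _hspaf(v: VariantRecord) -> Optional[float]:
    hs = highest_subpop_af(v.frequencies)
    return None if isinstance(hs, _Absent) else hs[1]


def _full_gain_support(v: VariantRecord, g: GeneConfig) -> bool:
    """Experimentally demonstrated qualifying gain-type effect, complete panel."""
    f = v.functional
    return (f.mechanism in (Mechanism.GOF, Mechanism.GOP)
            and f.mechanism in g.qualifying_mechanisms_for_pathogenic
            and f.evidence_level is EvidenceLevel.EXPERIMENTAL
            and not (f.assay_notes & _PARTIAL_PANEL_FLAGS))


def _full_loss_support(v: VariantRecord, g: GeneConfig) -> bool:
    """(Near-)complete functional loss, demonstrated or presumed."""
    f = v.functional
    return (f.mechanism is Mechanism.LOF
            and Mechanism.LOF in g.qualifying_mechanisms_for_pathogenic
            and f.loss_fraction is not None
            and f.loss_fraction >= g.pathogenic_min_loss
            and f.evidence_level in (EvidenceLevel.EXPERIMENTAL,
                                     EvidenceLevel.PRESUMED_COMPLETE))


def _partial_support(v: VariantRecord, g: GeneConfig) -> bool:
    """Functional support falling short of the pathogenic bar.

    Gain-type genes: an experimental qualifying assay with an incomplete
    panel.  LoF genes: a (near-)complete loss supported only by prediction.
    """
    f = v.functional
    if (f.mechanism in (Mechanism.GOF, Mechanism.GOP)
            and f.mechanism in g.qualifying_mechanisms_for_pathogenic
            and f.evidence_level is EvidenceLevel.EXPERIMENTAL
            and f.assay_notes & _PARTIAL_PANEL_FLAGS):
        return True
    if (f.mechanism is Mechanism.LOF
            and Mechanism.LOF in g.qualifying_mechanisms_for_pathogenic
            and f.loss_fraction is not None
            and f.loss_fraction >= g.pathogenic_min_loss
            and f.evidence_level is EvidenceLevel.PREDICTED):
        return True
    return False


def _base_qualifiers(v: VariantRecord) -> List[str]:
    """Qualifier components in their fixed order: detection note, odds ratio,
    mechanism/pathway note; a cystic-fibrosis legacy category leads."""
    quals: List[str] = []
    if v.cf_category:
        quals.append(v.cf_category)
    if v.detection_note:
        quals.append(v.detection_note)
    if v.or_point is not None:
        context = v.or_context or "the disease"
        s = f"odds ratio for {context}, {v.or_point:g}"
        if v.or_ci is not None:
            s += f" (95% CI {v.or_ci[0]:g}–{v.or_ci[1]:g})"
        quals.append(s)
    if v.mechanism_note:
        quals.append(v.mechanism_note)
    return quals


def classify_variant(v: VariantRecord, g: GeneConfig) -> ClassificationResult:
    """Classify one variant under its gene's five- or seven-category system."""
    if v.gene != g.gene:
        raise ValidationError(f"variant gene {v.gene} does not match config {g.gene}")
    if g.role is GeneRole.UNASSIGNED:
        raise UnassignedGeneRoleError(
            f"gene {g.gene} has no role: run the gene-level classification first")

    traces: List[RuleTrace] = []
    fired: List[str] = []
    flags: set = set()
    if v.risk_orientation_flipped:
        flags.add("risk_orientation_flipped")

    def trace(rule_id: str, outcome: str, **snapshot) -> None:
        fired.append(rule_id)
        traces.append(RuleTrace(rule_id=rule_id, inputs_snapshot=snapshot,
                                outcome=outcome))

    def result(category: Category, system: ClassificationSystem,
               qualifiers: List[str]) -> ClassificationResult:
        return ClassificationResult(
            category=category, system=system, qualifiers=tuple(qualifiers),
            fired_rules=tuple(fired), flags=frozenset(flags),
            traces=tuple(traces))

    trace("role-check", g.role.value, gene=g.gene)
    hspaf = _hspaf(v)
    quals = _base_qualifiers(v)

    if g.role is GeneRole.PREDISPOSING:
        system = ClassificationSystem.FIVE_CATEGORY
        if v.pathologically_relevant:
            if v.legacy_category is LegacyCategory.LIKELY_PATHOGENIC:
                cat = Category.LIKELY_PREDISPOSING
            else:
                cat = Category.PREDISPOSING
            trace("5C-relevant-predisposing", cat.value,
                  legacy=getattr(v.legacy_category, "value", None))
            return result(cat, system, quals)
        cat = _residual_category(v)
        trace("5C-nonrelevant", cat.value,
              legacy=getattr(v.legacy_category, "value", None))
        return result(cat, system, quals)

    # Seven-category ladder for causing genes.
    system = ClassificationSystem.SEVEN_CATEGORY
    f = v.functional

    # (1) protective alleles.
    if f.mechanism is Mechanism.PROTECTIVE_LOF:
        flags.add("protective")
        trace("7C-1-protective", Category.BENIGN.value, mechanism=f.mechanism.value)
        return result(Category.BENIGN, system, quals + [PROTECTIVE_QUALIFIER])

    # Frequency rules need frequency data (observed-absent counts as data).
    if v.pathologically_relevant and not v.frequencies.has_data:
        trace("7C-freq-missing", Category.VUS.value,
              note="insufficient frequency data")
        return result(Category.VUS, system, quals)

    very_rare = is_very_rare(v.frequencies, g.af_threshold) \
        if v.frequencies.has_data else False
    if hspaf is not None and hspaf >= g.af_threshold:
        flags.add("af_outlier")

    # (2) pathogenic.
    if very_rare and (_full_gain_support(v, g) or _full_loss_support(v, g)):
        trace("7C-2-pathogenic", Category.PATHOGENIC.value,
              hspAF=hspaf, loss=f.loss_fraction, mechanism=f.mechanism.value)
        return result(Category.PATHOGENIC, system, quals)

    # (3) likely pathogenic.
    if very_rare and v.pathologically_relevant and _partial_support(v, g):
        trace("7C-3-likely-pathogenic", Category.LIKELY_PATHOGENIC.value,
              hspAF=hspaf, loss=f.loss_fraction, mechanism=f.mechanism.value)
        return result(Category.LIKELY_PATHOGENIC, system, quals)

    # (4) predisposing.
    if v.pathologically_relevant:
        common = hspaf is not None and hspaf >= g.af_threshold
        in_band = (f.loss_fraction is not None
                   and g.predisposing_min_loss < f.loss_fraction < g.pathogenic_min_loss)
        if common or in_band:
            trace("7C-4-predisposing", Category.PREDISPOSING.value,
                  hspAF=hspaf, loss=f.loss_fraction)
            return result(Category.PREDISPOSING, system, quals)

    # (5) likely predisposing: suggestive, non-experimental support only.
    if (v.pathologically_relevant
            and f.evidence_level is EvidenceLevel.PREDICTED
            and f.mechanism is not Mechanism.NEUTRAL):
        trace("7C-5-likely-predisposing", Category.LIKELY_PREDISPOSING.value,
              mechanism=f.mechanism.value)
        return result(Category.LIKELY_PREDISPOSING, system, quals)

    cat = _residual_category(v)
    trace("7C-6-residual", cat.value,
          legacy=getattr(v.legacy_category, "value", None))
    return result(cat, system, quals)


def _residual_category(v: VariantRecord) -> Category:
    f = v.functional
    if f.mechanism is Mechanism.NEUTRAL:
        if f.evidence_level is EvidenceLevel.EXPERIMENTAL:
            return Category.BENIGN
        if f.evidence_level is EvidenceLevel.PREDICTED:
            return Category.LIKELY_BENIGN
    if v.legacy_category in (LegacyCategory.BENIGN, LegacyCategory.LIKELY_BENIGN,
                             LegacyCategory.VUS):
        return Category(v.legacy_category.value)
    return Category.VUS


_CATEGORY_DISPLAY = {
    Category.PATHOGENIC: "Pathogenic",
    Category.LIKELY_PATHOGENIC: "Likely pathogenic",
    Category.PREDISPOSING: "Predisposing",
    Category.LIKELY_PREDISPOSING: "Likely predisposing",
    Category.VUS: "VUS",
    Category.LIKELY_BENIGN: "Likely benign",
    Category.BENIGN: "Benign",
}


def build_annotation(r: ClassificationResult, v: Optional[VariantRecord] = None) -> str:
    """Render ``"<Category> (<qualifier; qualifier; ...>)"``.

    Qualifiers were assembled by :func:`classify_variant` in their fixed
    order (detection-frequency note, odds ratio with CI, mechanism/pathway
    note).  An empty qualifier list yields the bare category.
    """
    display = _CATEGORY_DISPLAY[r.category]
    if not r.qualifiers:
        return display
    return f"{display} ({'; '.join(r.qualifiers)})"
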