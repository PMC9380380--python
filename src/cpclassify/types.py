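"""Core domain types for gene-aware variant classification.

The framework distinguishes disease-*causing* genes (a single severe variant
can produce the disease, e.g. autosomal dominant hereditary pancreatitis from
*PRSS1*) from disease-*predisposing* genes (even the most deleterious variant
only raises risk, e.g. *CFTR* in chronic pancreatitis).  Variants in causing
genes are classified on a seven-category scale (pathogenic, likely pathogenic,
predisposing, likely predisposing, VUS, likely benign, benign); variants in
predisposing genes on a five-category scale in which "pathogenic"/"likely
pathogenic" are replaced by "predisposing"/"likely predisposing".

Population allele frequencies follow the gnomAD convention of a global
frequency plus per-subpopulation frequencies.  A frequency can be a float in
[0, 1], the sentinel :data:`ABSENT` (the allele was looked for and not seen),
or simply missing (never measured).  The distinction matters: an allele that
is absent from gnomAD is *very rare* by definition, whereas a variant with no
frequency data at all cannot be frequency-filtered and degrades to VUS when a
frequency rule is consulted.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class _Absent:
    """Singleton sentinel: allele observed to be absent from a population."""

    _instance: Optional["_Absent"] = None

    def __new__(cls) -> "_Absent":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "Absent"

    def __reduce__(self):
        return (_Absent, ())


ABSENT = _Absent()

#: A population allele frequency: a fraction, or observed-absent.
Frequency = Union[float, _Absent]

#: gnomAD v2 continental subpopulation codes.
SUBPOPULATIONS: Tuple[str, ...] = (
    "AFR", "AMR", "ASJ", "EAS", "FIN", "NFE", "SAS", "OTH",
)


class Mechanism(str, enum.Enum):
    """Functional consequence class of a pathologically relevant variant."""

    GOF = "GoF"                      # gain of function (e.g. increased trypsinogen activation/stability)
    LOF = "LoF"                      # loss of function
    GOP = "GoP"                      # gain of proteotoxicity (misfolding, ER stress)
    PROTECTIVE_LOF = "protective_LoF"  # loss of function that protects against disease
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


class EvidenceLevel(str, enum.Enum):
    EXPERIMENTAL = "experimental"
    PRESUMED_COMPLETE = "presumed_complete"  # pLoF: presumed complete functional loss
    PREDICTED = "predicted"
    NONE = "none"


#: Recognised functional-assay annotation flags.
ASSAY_FLAGS = frozenset({
    "increased_activation",
    "increased_stability",
    "reduced_secretion",
    "er_stress_marker",
    "secretion_moderate_impact",
    "er_stress_untested",
})


class Category(str, enum.Enum):
    """Framework variant categories (superset of the five ACMG tiers)."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PREDISPOSING = "predisposing"
    LIKELY_PREDISPOSING = "likely_predisposing"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


class LegacyCategory(str, enum.Enum):
    """Classification carried over from an upstream database (ACMG five tiers
    plus the 'protective' category used by the Genetic Risk Factors in
    Chronic Pancreatitis Database)."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    PROTECTIVE = "protective"


class GeneRole(str, enum.Enum):
    CAUSING = "causing"
    PREDISPOSING = "predisposing"
    UNASSIGNED = "unassigned"


class ClassificationSystem(str, enum.Enum):
    FIVE_CATEGORY = "five_category"
    SEVEN_CATEGORY = "seven_category"


class KnockoutPhenotype(str, enum.Enum):
    SEVERE_EARLY = "severe_early"
    MILD_LATE = "mild_late"
    NONE_OBSERVED = "none_observed"
    UNKNOWN = "unknown"


class Subtype(str, enum.Enum):
    """Chronic pancreatitis clinical subtypes."""

    HCP = "HCP"  # hereditary: >=3 affected members over >=2 generations
    FCP = "FCP"  # familial: positive history short of HCP criteria
    ICP = "ICP"  # idiopathic: no family history, no external factor
    ACP = "ACP"  # alcoholic


class Verdict(str, enum.Enum):
    SUPPORTS_CAUSING = "supports_causing"
    SUPPORTS_PREDISPOSING = "supports_predisposing"
    NEUTRAL = "neutral"
    INAPPLICABLE = "inapplicable"


_HGVS_RE = re.compile(r"^[cgmnr]\.\S+$")
_PROTEIN_HGVS_RE = re.compile(r"^p\.\S+$")


def _check_fraction(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def _as_frequency(value: Frequency, name: str) -> None:
    if isinstance(value, _Absent):
        return
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(f"{name} must be a fraction or ABSENT, got {value!r}")
    _check_fraction(float(value), name)


@dataclass(frozen=True)
class PopulationFrequencySet:
    """Global and per-subpopulation allele frequencies for one variant.

    ``subpop_afs`` maps subpopulation code to a frequency or :data:`ABSENT`;
    a code missing from the map was not measured.  ``partitions_global``
    declares that the stored subpopulations partition the global sample, which
    enables the sanity check min(subpop) <= global <= max(subpop).
    """

    variant_key: str
    global_af: Optional[Frequency] = None
    subpop_afs: Mapping[str, Frequency] = field(default_factory=dict)
    source_note: str = ""
    partitions_global: bool = False

    def __post_init__(self) -> None:
        if not self.variant_key:
            raise ValidationError("variant_key must be non-empty")
        if self.global_af is not None:
            _as_frequency(self.global_af, "global_af")
        for code, af in self.subpop_afs.items():
            if code not in SUBPOPULATIONS:
                raise ValidationError(f"unknown subpopulation code {code!r}")
            _as_frequency(af, f"subpop_afs[{code}]")
        object.__setattr__(self, "subpop_afs", dict(self.subpop_afs))
        if self.partitions_global:
            present = [float(v) for v in self.subpop_afs.values()
                       if not isinstance(v, _Absent)]
            if (len(present) == len(SUBPOPULATIONS)
                    and self.global_af is not None
                    and not isinstance(self.global_af, _Absent)):
                g = float(self.global_af)
                if not (min(present) <= g <= max(present)):
                    raise ValidationError(
                        f"global_af {g} outside subpopulation range "
                        f"[{min(present)}, {max(present)}] for {self.variant_key}")

    @property
    def has_data(self) -> bool:
        """True when any frequency (including observed-absent) is recorded."""
        return self.global_af is not None or bool(self.subpop_afs)

    def present_subpops(self) -> dict[str, float]:
        """Subpopulations with a numeric (non-absent) frequency."""
        return {c: float(v) for c, v in self.subpop_afs.items()
                if not isinstance(v, _Absent)}


@dataclass(frozen=True)
class FunctionalEvidence:
    """Mechanism and quantitative functional impact of a variant.

    ``loss_fraction`` is the fractional loss of normal protein function and
    is only defined for (protective) loss-of-function variants; gain-type
    effects are not quantifiable on this scale.
    """

    mechanism: Mechanism = Mechanism.UNKNOWN
    loss_fraction: Optional[float] = None
    evidence_level: EvidenceLevel = EvidenceLevel.NONE
    assay_notes: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay_notes", frozenset(self.assay_notes))
        bad = self.assay_notes - ASSAY_FLAGS
        if bad:
            raise ValidationError(f"unknown assay flags: {sorted(bad)}")
        if self.loss_fraction is not None:
            _check_fraction(self.loss_fraction, "loss_fraction")
            if self.mechanism not in (Mechanism.LOF, Mechanism.PROTECTIVE_LOF,
                                      Mechanism.NEUTRAL):
                raise ValidationError(
                    f"loss_fraction is only meaningful for LoF-type mechanisms, "
                    f"not {self.mechanism.value}")
        if self.mechanism is Mechanism.NEUTRAL and self.loss_fraction not in (None, 0.0):
            raise ValidationError("a neutral variant cannot have a functional loss")
        if (self.evidence_level is EvidenceLevel.PRESUMED_COMPLETE
                and self.loss_fraction != 1.0):
            raise ValidationError(
                "evidence_level=presumed_complete implies loss_fraction=1.0")


@dataclass(frozen=True)
class PedigreeSummary:
    n_affected: int = 0
    n_generations: int = 0
    relationship_note: str = ""

    def __post_init__(self) -> None:
        if self.n_affected < 0 or self.n_generations < 0:
            raise ValidationError("pedigree counts must be nonnegative")
        if self.n_affected >= 1 and self.n_generations < 1:
            raise ValidationError("an affected pedigree spans at least one generation")


@dataclass(frozen=True)
class GeneEvidence:
    """Gene-level evidence feeding the causing-vs-predisposing decision."""

    gene: str
    n_very_rare_mendelian_variants: Optional[int] = None
    largest_pedigree: Optional[PedigreeSummary] = None
    oe_plof: Optional[float] = None
    oe_ci: Tuple[Optional[float], Optional[float]] = (None, None)
    aggregate_or: Optional[float] = None
    aggregate_or_ci: Tuple[Optional[float], Optional[float]] = (None, None)
    knockout_phenotype: KnockoutPhenotype = KnockoutPhenotype.UNKNOWN
    primary_mechanism: Mechanism = Mechanism.UNKNOWN
    has_pathologically_relevant_variants: bool = True
    context_note: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        n = self.n_very_rare_mendelian_variants
        if n is not None and (not isinstance(n, int) or n < 0):
            raise ValidationError("variant census must be a nonnegative integer")
        for point, (lo, hi), label in (
                (self.oe_plof, self.oe_ci, "o/e"),
                (self.aggregate_or, self.aggregate_or_ci, "aggregate OR")):
            if point is not None and point < 0:
                raise ValidationError(f"{label} must be nonnegative")
            if lo is not None and hi is not None and point is not None:
                if not (lo <= point <= hi):
                    raise ValidationError(
                        f"{label} CI [{lo}, {hi}] must bracket the point {point}")


@dataclass(frozen=True)
class GeneConfig:
    """Per-gene classification policy: role plus the two thresholds."""

    gene: str
    mrna_accession: str = ""
    role: GeneRole = GeneRole.UNASSIGNED
    af_threshold: float = 0.001
    pathogenic_min_loss: float = 0.95
    predisposing_min_loss: float = 0.10
    qualifying_mechanisms_for_pathogenic: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        if not (0.0 < self.af_threshold < 1.0):
            raise ValidationError("af_threshold must lie in (0, 1)")
        if not (0.0 < self.predisposing_min_loss < self.pathogenic_min_loss <= 1.0):
            raise ValidationError(
                "need 0 < predisposing_min_loss < pathogenic_min_loss <= 1")
        mechs = frozenset(Mechanism(m) for m in self.qualifying_mechanisms_for_pathogenic)
        object.__setattr__(self, "qualifying_mechanisms_for_pathogenic", mechs)


@dataclass(frozen=True)
class VariantRecord:
    """One variant: identity, frequencies, functional evidence, annotations.

    ``structural`` marks copy-number / hybrid alleles whose identity is a
    whitespace-free label rather than an HGVS string.
    """

    gene: str
    cdna_hgvs: str
    frequencies: PopulationFrequencySet
    protein_hgvs: Optional[str] = None
    functional: FunctionalEvidence = FunctionalEvidence()
    legacy_category: Optional[LegacyCategory] = None
    or_point: Optional[float] = None
    or_ci: Optional[Tuple[float, float]] = None
    or_context: str = ""
    pathologically_relevant: bool = False
    gold_standard: bool = False
    mendelian_context: Optional[PedigreeSummary] = None
    detection_note: str = ""
    mechanism_note: str = ""
    cf_category: str = ""
    structural: bool = False
    risk_orientation_flipped: bool = False
    coords: Optional[Tuple[str, int, str, str]] = None  # (chrom, pos, ref, alt)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        if not self.cdna_hgvs or any(ch.isspace() for ch in self.cdna_hgvs):
            raise ValidationError(
                f"variant identity must be non-empty without whitespace: {self.cdna_hgvs!r}")
        if not self.structural and not _HGVS_RE.match(self.cdna_hgvs):
            raise ValidationError(f"malformed cDNA HGVS string: {self.cdna_hgvs!r}")
        if self.protein_hgvs is not None and not _PROTEIN_HGVS_RE.match(self.protein_hgvs):
            raise ValidationError(f"malformed protein HGVS string: {self.protein_hgvs!r}")
        if self.gold_standard and not self.pathologically_relevant:
            raise ValidationError("a gold-standard variant is pathologically relevant")
        if self.or_point is not None and self.or_point <= 0:
            raise ValidationError("odds ratio must be positive")
        if self.or_ci is not None:
            lo, hi = self.or_ci
            if not (0 < lo <= hi):
                raise ValidationError("odds-ratio CI must be positive and ordered")

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.cdna_hgvs}"


@dataclass(frozen=True)
class RuleTrace:
    rule_id: str
    inputs_snapshot: Mapping[str, object] = field(default_factory=dict)
    outcome: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs_snapshot", dict(self.inputs_snapshot))


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of classifying one variant, with its audit trail."""

    category: Category
    system: ClassificationSystem
    qualifiers: Tuple[str, ...] = ()
    fired_rules: Tuple[str, ...] = ()
    flags: frozenset = frozenset()
    traces: Tuple[RuleTrace, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualifiers", tuple(self.qualifiers))
        object.__setattr__(self, "fired_rules", tuple(self.fired_rules))
        object.__setattr__(self, "flags", frozenset(self.flags))
        object.__setattr__(self, "traces", tuple(self.traces))
        if self.system is ClassificationSystem.FIVE_CATEGORY and self.category in (
                Category.PATHOGENIC, Category.LIKELY_PATHOGENIC):
            raise ValidationError(
                "five-category system never assigns pathogenic/likely pathogenic")
        if self.category is not Category.VUS and not self.fired_rules:
            raise ValidationError("a non-VUS category must cite at least one rule")


@dataclass(frozen=True)
class GeneRoleDecision:
    """Gene-level role assignment with an auditable evidence trail."""

    gene: str
    role: GeneRole
    evidence_lines: Tuple[Tuple[str, Verdict, str], ...]
    decisive_criterion: Optional[str] = None
    conflict_warning: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence_lines", tuple(self.evidence_lines))
        if not self.evidence_lines:
            raise ValidationError("a decision must record at least one evidence line")
        if self.role is not GeneRole.UNASSIGNED and self.decisive_criterion is None:
            raise ValidationError("an assigned role needs a decisive criterion")


@dataclass(frozen=True)
class GoldStandardAudit:
    """Population-presence census of the gold-standard calibration set."""

    n_total: int
    n_present_in_population: int
    max_hspaf_variant: Optional[str]
    max_hspaf: Optional[float]
    outliers: Tuple[Tuple[str, float], ...]
    threshold_used: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "outliers", tuple(self.outliers))
        if self.n_present_in_population > self.n_total:
            raise ValidationError("present count cannot exceed total")
        for key, af in self.outliers:
            if af < self.threshold_used:
                raise ValidationError(
                    f"outlier {key} has hspAF {af} below threshold {self.threshold_used}")

    @property
    def fraction_present(self) -> float:
        return self.n_present_in_population / self.n_total


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-status 2x2 table for odds-ratio estimation."""

    case_carrier: int
    case_noncarrier: int
    control_carrier: int
    control_noncarrier: int

    def __post_init__(self) -> None:
        cells = (self.case_carrier, self.case_noncarrier,
                 self.control_carrier, self.control_noncarrier)
        for c in cells:
            if not isinstance(c, int) or isinstance(c, bool) or c < 0:
                raise ValidationError("cell counts must be nonnegative integers")
        if self.case_carrier + self.case_noncarrier == 0:
            raise ValidationError("need at least one case")
        if self.control_carrier + self.control_noncarrier == 0:
            raise ValidationError("need at least one control")


@dataclass(frozen=True)
class OddsRatioEstimate:
    or_point: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    correction_applied: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValidationError("CI must bracket the point estimate")
        if self.or_point <= 0 or self.ci_low <= 0:
            raise ValidationError("odds ratios are positive")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
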