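"""Loaders for the packaged evidence tables.

Every fixture is shipped as UTF-8 TSV/JSON with a SHA-256 manifest
(``manifest.json``); loading verifies the checksum first, so an edited or
corrupted fixture fails fast with an :class:`IntegrityError`, and row-level
validation failures name the offending row.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from ..io import read_variant_tsv
from ..types import (
    Category,
    GeneConfig,
    GeneEvidence,
    GeneRole,
    KnockoutPhenotype,
    Mechanism,
    PedigreeSummary,
    ValidationError,
    VariantRecord,
)

_DATA_DIR = Path(__file__).parent / "data"

TABLE_IDS = ("T1", "T2", "T3", "T4", "T5", "T6")


class IntegrityError(ValidationError):
    """A packaged fixture does not match its frozen checksum or schema."""


@dataclass(frozen=True)
class GeneInfo:
    """One row of the gene-facts table."""

    gene: str
    mrna_accession: str
    year_discovered: int
    coding_bp: int
    protein_aa: int
    mechanisms: Tuple[Mechanism, ...]
    oe_plof: float
    oe_ci: Tuple[float, float]


@dataclass(frozen=True)
class AnnotationExample:
    """Qualifier components for one published annotation example."""

    gene: str
    variant_label: str
    category: Category
    detection_note: str
    or_context: str
    or_point: Optional[float]
    mechanism_note: str
    protective: bool


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _verify(filename: str) -> Path:
    path = _DATA_DIR / filename
    if not path.exists():
        raise IntegrityError(f"packaged fixture {filename} is missing")
    manifest = json.loads((_DATA_DIR / "manifest.json").read_text())
    expected = manifest.get(filename)
    if expected is None:
        raise IntegrityError(f"{filename} has no entry in the checksum manifest")
    actual = _sha256(path)
    if actual != expected:
        raise IntegrityError(
            f"checksum mismatch for {filename}: expected {expected}, got {actual}")
    return path


def _load_t1(path: Path) -> List[GeneInfo]:
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                rows.append(GeneInfo(
                    gene=row["gene"],
                    mrna_accession=row["mrna_accession"],
                    year_discovered=int(row["year_discovered"]),
                    coding_bp=int(row["coding_bp"]),
                    protein_aa=int(row["protein_aa"]),
                    mechanisms=tuple(Mechanism(m)
                                     for m in row["mechanisms"].split("|")),
                    oe_plof=float(row["oe_plof"]),
                    oe_ci=(float(row["oe_ci_low"]), float(row["oe_ci_high"])),
                ))
            except (KeyError, ValueError) as exc:
                raise IntegrityError(f"{path.name}:{i}: {exc}") from None
    return rows


def _load_t6(path: Path) -> List[AnnotationExample]:
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                rows.append(AnnotationExample(
                    gene=row["gene"],
                    variant_label=row["variant_label"],
                    category=Category(row["category"]),
                    detection_note=row["detection_note"],
                    or_context=row["or_context"],
                    or_point=float(row["or_point"]) if row["or_point"] else None,
                    mechanism_note=row["mechanism_note"],
                    protective=row["protective"].lower() == "true",
                ))
            except (KeyError, ValueError) as exc:
                raise IntegrityError(f"{path.name}:{i}: {exc}") from None
    return rows


def load_bundled_tables(table_id: str):
    """Load one packaged table as fully validated typed records.

    ``T1`` yields :class:`GeneInfo`, ``T2``–``T5`` yield
    :class:`~cpclassify.types.VariantRecord`, ``T6`` yields
    :class:`AnnotationExample`.
    """
    if table_id not in TABLE_IDS:
        raise ValidationError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
    path = _verify(f"{table_id}.tsv")
    if table_id == "T1":
        return _load_t1(path)
    if table_id == "T6":
        return _load_t6(path)
    try:
        return read_variant_tsv(path)
    except ValidationError as exc:
        raise IntegrityError(str(exc)) from None


def parse_gene_evidence(payload: dict) -> Dict[str, GeneEvidence]:
    """Parse a gene-evidence JSON payload (the genes.json schema)."""
    out: Dict[str, GeneEvidence] = {}
    for gene, ev in payload["evidence"].items():
        pedigree = ev.get("largest_pedigree")
        out[gene] = GeneEvidence(
            gene=gene,
            n_very_rare_mendelian_variants=ev["n_very_rare_mendelian_variants"],
            largest_pedigree=PedigreeSummary(**pedigree) if pedigree else None,
            oe_plof=ev["oe_plof"],
            oe_ci=tuple(ev["oe_ci"]),
            aggregate_or=ev["aggregate_or"],
            aggregate_or_ci=tuple(ev["aggregate_or_ci"]),
            knockout_phenotype=KnockoutPhenotype(ev["knockout_phenotype"]),
            primary_mechanism=Mechanism(ev["primary_mechanism"]),
            has_pathologically_relevant_variants=ev["has_pathologically_relevant_variants"],
            context_note=ev.get("context_note", ""),
        )
    return out


def load_gene_evidence() -> Dict[str, GeneEvidence]:
    """The packaged four-gene evidence set (census, o/e, ORs, knockouts)."""
    return parse_gene_evidence(json.loads(_verify("genes.json").read_text()))


def load_gene_configs() -> Dict[str, GeneConfig]:
    """The packaged per-gene classification policies (role + thresholds)."""
    payload = json.loads(_verify("genes.json").read_text())
    out: Dict[str, GeneConfig] = {}
    for gene, cfg in payload["configs"].items():
        out[gene] = GeneConfig(
            gene=gene,
            mrna_accession=cfg["mrna_accession"],
            role=GeneRole(cfg["role"]),
            af_threshold=cfg["af_threshold"],
            pathogenic_min_loss=cfg["pathogenic_min_loss"],
            predisposing_min_loss=cfg["predisposing_min_loss"],
            qualifying_mechanisms_for_pathogenic=frozenset(
                Mechanism(m) for m in cfg["qualifying_mechanisms_for_pathogenic"]),
        )
    return out


def load_reclassification_set() -> List[VariantRecord]:
    """Variant inputs for the published worked reclassifications."""
    path = _verify("reclassification.tsv")
    try:
        return read_variant_tsv(path)
    except ValidationError as exc:
        raise IntegrityError(str(exc)) from None
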