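"""Readers and writers for the tool's interchange formats.

The canonical interchange format is a versioned, tab-delimited variant table
(UTF-8, header row); VCF is accepted as input sugar for call sets annotated
with gnomAD-style per-subpopulation allele-frequency INFO keys.  Frequency
cells distinguish three states: a numeric fraction, the literal ``Absent``
(looked for, not found), and an empty cell (never measured).

All writers are deterministic: stable column order and floats rendered with
six significant digits (enough to preserve printed gnomAD values such as
0.0007018 exactly).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .types import (
    ABSENT,
    Category,
    ClassificationResult,
    EvidenceLevel,
    Frequency,
    LegacyCategory,
    Mechanism,
    PedigreeSummary,
    PopulationFrequencySet,
    SUBPOPULATIONS,
    ValidationError,
    VariantRecord,
    _Absent,
)

SCHEMA_VERSION = "1"

_FREQ_COLUMNS = {code: f"af_{code.lower()}" for code in SUBPOPULATIONS}

#: Column order of the versioned variant TSV schema.
VARIANT_COLUMNS: Tuple[str, ...] = (
    "gene", "cdna_hgvs", "protein_hgvs", "structural",
    "mechanism", "loss_fraction", "evidence_level", "assay_notes",
    "legacy_category",
    "gpaf", *(_FREQ_COLUMNS[c] for c in SUBPOPULATIONS),
    "or_point", "or_ci_low", "or_ci_high", "or_context",
    "pathologically_relevant", "gold_standard",
    "n_families", "pedigree_n_affected", "pedigree_n_generations", "pedigree_note",
    "detection_note", "mechanism_note", "cf_category", "source_note",
)

_MANDATORY = ("gene", "cdna_hgvs")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, _Absent):
        return "Absent"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _parse_freq(cell: str, where: str) -> Optional[Frequency]:
    cell = cell.strip()
    if not cell:
        return None
    if cell.lower() == "absent":
        return ABSENT
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"{where}: malformed frequency {cell!r}") from None


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in ("true", "1", "yes")


def _parse_float(cell: str, where: str) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"{where}: malformed number {cell!r}") from None


def _parse_int(cell: str, where: str) -> Optional[int]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return int(cell)
    except ValueError:
        raise ValidationError(f"{where}: malformed integer {cell!r}") from None


def _row_to_record(row: Mapping[str, str], where: str) -> VariantRecord:
    row = {k: (v or "") for k, v in row.items() if k is not None}
    gene = row.get("gene", "").strip()
    cdna = row.get("cdna_hgvs", "").strip()
    if not gene or not cdna:
        raise ValidationError(f"{where}: gene and cdna_hgvs are mandatory")

    subpop_afs: Dict[str, Frequency] = {}
    for code in SUBPOPULATIONS:
        parsed = _parse_freq(row.get(_FREQ_COLUMNS[code], ""), where)
        if parsed is not None:
            subpop_afs[code] = parsed
    freqs = PopulationFrequencySet(
        variant_key=f"{gene}:{cdna}",
        global_af=_parse_freq(row.get("gpaf", ""), where),
        subpop_afs=subpop_afs,
        source_note=row.get("source_note", "").strip(),
    )

    mech = row.get("mechanism", "").strip()
    level = row.get("evidence_level", "").strip()
    notes = frozenset(p for p in row.get("assay_notes", "").split("|") if p)
    try:
        functional_kwargs = dict(
            mechanism=Mechanism(mech) if mech else Mechanism.UNKNOWN,
            loss_fraction=_parse_float(row.get("loss_fraction", ""), where),
            evidence_level=EvidenceLevel(level) if level else EvidenceLevel.NONE,
            assay_notes=notes,
        )
        legacy = row.get("legacy_category", "").strip()
        or_lo = _parse_float(row.get("or_ci_low", ""), where)
        or_hi = _parse_float(row.get("or_ci_high", ""), where)
        n_aff = _parse_int(row.get("pedigree_n_affected", ""), where)
        n_gen = _parse_int(row.get("pedigree_n_generations", ""), where)
        pedigree = None
        if n_aff is not None or n_gen is not None:
            pedigree = PedigreeSummary(
                n_affected=n_aff or 0, n_generations=n_gen or 0,
                relationship_note=row.get("pedigree_note", "").strip())
        from .types import FunctionalEvidence  # local to keep import graph flat
        return VariantRecord(
            gene=gene,
            cdna_hgvs=cdna,
            protein_hgvs=row.get("protein_hgvs", "").strip() or None,
            frequencies=freqs,
            functional=FunctionalEvidence(**functional_kwargs),
            legacy_category=LegacyCategory(legacy) if legacy else None,
            or_point=_parse_float(row.get("or_point", ""), where),
            or_ci=(or_lo, or_hi) if or_lo is not None and or_hi is not None else None,
            or_context=row.get("or_context", "").strip(),
            pathologically_relevant=_parse_bool(row.get("pathologically_relevant", "")),
            gold_standard=_parse_bool(row.get("gold_standard", "")),
            mendelian_context=pedigree,
            detection_note=row.get("detection_note", "").strip(),
            mechanism_note=row.get("mechanism_note", "").strip(),
            cf_category=row.get("cf_category", "").strip(),
            structural=_parse_bool(row.get("structural", "")),
        )
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from None


def read_variant_tsv(path: Union[str, Path],
                     schema_version: str = SCHEMA_VERSION) -> List[VariantRecord]:
    """Read a versioned variant TSV into validated :class:`VariantRecord`\\ s.

    Validation failures carry the offending row number.  Unknown columns are
    warned about and ignored; missing mandatory columns are an error.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise ValidationError(f"{path.name}: missing mandatory columns {missing}")
        unknown = [c for c in header if c not in VARIANT_COLUMNS]
        if unknown:
            warnings.warn(f"{path.name}: ignoring unknown columns {unknown}",
                          stacklevel=2)
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            records.append(_row_to_record(row, f"{path.name}:{i}"))
    return records


def write_variant_tsv(records: Sequence[VariantRecord],
                      path: Union[str, Path]) -> None:
    """Write records to the versioned TSV schema (deterministic output)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for rec in records:
            row = {
                "gene": rec.gene,
                "cdna_hgvs": rec.cdna_hgvs,
                "protein_hgvs": rec.protein_hgvs,
                "structural": rec.structural or None,
                "mechanism": rec.functional.mechanism.value
                if rec.functional.mechanism is not Mechanism.UNKNOWN else "",
                "loss_fraction": rec.functional.loss_fraction,
                "evidence_level": rec.functional.evidence_level.value
                if rec.functional.evidence_level is not EvidenceLevel.NONE else "",
                "assay_notes": "|".join(sorted(rec.functional.assay_notes)),
                "legacy_category": rec.legacy_category.value if rec.legacy_category else "",
                "gpaf": rec.frequencies.global_af,
                "or_point": rec.or_point,
                "or_ci_low": rec.or_ci[0] if rec.or_ci else None,
                "or_ci_high": rec.or_ci[1] if rec.or_ci else None,
                "or_context": rec.or_context,
                "pathologically_relevant": rec.pathologically_relevant or None,
                "gold_standard": rec.gold_standard or None,
                "n_families": "",
                "pedigree_n_affected": rec.mendelian_context.n_affected
                if rec.mendelian_context else None,
                "pedigree_n_generations": rec.mendelian_context.n_generations
                if rec.mendelian_context else None,
                "pedigree_note": rec.mendelian_context.relationship_note
                if rec.mendelian_context else "",
                "detection_note": rec.detection_note,
                "mechanism_note": rec.mechanism_note,
                "cf_category": rec.cf_category,
                "source_note": rec.frequencies.source_note,
            }
            for code in SUBPOPULATIONS:
                row[_FREQ_COLUMNS[code]] = rec.frequencies.subpop_afs.get(code)
            writer.writerow([_fmt(row.get(col, "")) for col in VARIANT_COLUMNS])


# ---------------------------------------------------------------------------
# Classification-result output


def write_results(results: Sequence[Tuple[VariantRecord, ClassificationResult]],
                  path: Union[str, Path], fmt: str = "tsv") -> None:
    """Write (variant, result) pairs as TSV or JSON, with the rendered
    annotation string included."""
    from .varclass import build_annotation
    path = Path(path)
    rows = []
    for rec, res in results:
        rows.append({
            "variant": rec.key,
            "category": res.category.value,
            "system": res.system.value,
            "qualifiers": list(res.qualifiers),
            "fired_rules": list(res.fired_rules),
            "flags": sorted(res.flags),
            "annotation": build_annotation(res, rec),
        })
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    elif fmt == "tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            cols = ("variant", "category", "system", "qualifiers",
                    "fired_rules", "flags", "annotation")
            writer.writerow(cols)
            for row in rows:
                writer.writerow([
                    "|".join(row[c]) if isinstance(row[c], list) else row[c]
                    for c in cols])
    else:
        raise ValidationError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class FrequencyFieldMap:
    """Mapping from subpopulation codes to VCF INFO keys (gnomAD dialect)."""

    global_key: str = "AF"
    subpop_keys: Mapping[str, str] = field(default_factory=lambda: {
        code: f"AF_{code.lower()}" for code in SUBPOPULATIONS})

    def __post_init__(self) -> None:
        object.__setattr__(self, "subpop_keys", dict(self.subpop_keys))
        for code in self.subpop_keys:
            if code not in SUBPOPULATIONS:
                raise ValidationError(f"unknown subpopulation code {code!r}")
        keys = [self.global_key, *self.subpop_keys.values()]
        if len(set(keys)) != len(keys):
            raise ValidationError("INFO keys must be unique")


def read_variant_vcf(path: Union[str, Path],
                     fmap: Optional[FrequencyFieldMap] = None,
                     gene_field: str = "GENE",
                     cdna_field: str = "CDNA",
                     protein_field: str = "PROT") -> List[VariantRecord]:
    """Read a VCF into variant records, one per (biallelic) site.

    Frequencies come from gnomAD-style INFO keys via ``fmap``; a missing key
    is recorded as observed-absent, a malformed value triggers a per-record
    warning and is recorded as observed-absent.  Multi-allelic sites must be
    split upstream.  Coordinates are preserved but classification is driven
    by the HGVS identity.
    """
    import pysam

    fmap = fmap or FrequencyFieldMap()
    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            if site.alts is None or len(site.alts) != 1:
                raise ValidationError(
                    f"multi-allelic site {site.chrom}:{site.pos} must be split")

            def info_get(key: str, site=site):
                try:
                    value = site.info.get(key)
                except (KeyError, ValueError):  # key absent from the header
                    return None
                return value

            def info_freq(key: str, site=site) -> Frequency:
                raw = info_get(key, site)
                if raw is None:
                    return ABSENT
                if isinstance(raw, (tuple, list)):
                    raw = raw[0]
                try:
                    value = float(raw)
                except (TypeError, ValueError):
                    warnings.warn(
                        f"{site.chrom}:{site.pos}: malformed {key}={raw!r}, "
                        "treating as absent", stacklevel=2)
                    return ABSENT
                if not (0.0 <= value <= 1.0):
                    warnings.warn(
                        f"{site.chrom}:{site.pos}: out-of-range {key}={value}, "
                        "treating as absent", stacklevel=2)
                    return ABSENT
                # htslib stores floats at single precision; restore the
                # 6-significant-digit value the annotation was written with
                return float(f"{value:.6g}")

            gene = info_get(gene_field)
            if gene is None:
                raise ValidationError(
                    f"{site.chrom}:{site.pos}: missing INFO/{gene_field}")
            if isinstance(gene, tuple):
                gene = gene[0]
            cdna = info_get(cdna_field)
            if isinstance(cdna, tuple):
                cdna = cdna[0]
            if cdna is None:
                cdna = f"g.{site.pos}{site.ref}>{site.alts[0]}"
            prot = info_get(protein_field)
            if isinstance(prot, tuple):
                prot = prot[0]
            freqs = PopulationFrequencySet(
                variant_key=f"{gene}:{cdna}",
                global_af=info_freq(fmap.global_key),
                subpop_afs={code: info_freq(key)
                            for code, key in fmap.subpop_keys.items()},
                source_note="VCF import",
            )
            records.append(VariantRecord(
                gene=str(gene), cdna_hgvs=str(cdna),
                protein_hgvs=str(prot) if prot else None,
                frequencies=freqs,
                coords=(site.chrom, site.pos, site.ref, site.alts[0]),
            ))
    return records


def write_variant_vcf(records: Sequence[VariantRecord],
                      path: Union[str, Path],
                      fmap: Optional[FrequencyFieldMap] = None,
                      gene_field: str = "GENE",
                      cdna_field: str = "CDNA",
                      protein_field: str = "PROT") -> None:
    """Write records (which must carry coordinates) as a minimal VCF 4.2.

    Observed-absent and unmeasured frequencies are both rendered as a missing
    INFO key (VCF cannot distinguish them); a read-back therefore reports
    observed-absent for either.
    """
    import pysam

    fmap = fmap or FrequencyFieldMap()
    header = pysam.VariantHeader()
    contigs = []
    for rec in records:
        if rec.coords is None:
            raise ValidationError(f"{rec.key} has no coordinates; cannot write VCF")
        if rec.coords[0] not in contigs:
            contigs.append(rec.coords[0])
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add(fmap.global_key, "A", "Float", "Global allele frequency")
    for code, key in fmap.subpop_keys.items():
        header.info.add(key, "A", "Float", f"{code} subpopulation allele frequency")
    header.info.add(gene_field, "1", "String", "Gene symbol")
    header.info.add(cdna_field, "1", "String", "cDNA HGVS")
    header.info.add(protein_field, "1", "String", "Protein HGVS")

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            chrom, pos, ref, alt = rec.coords
            site = out.new_record(contig=chrom, start=pos - 1,
                                  stop=pos - 1 + len(ref),
                                  alleles=(ref, alt))
            site.info[gene_field] = rec.gene
            site.info[cdna_field] = rec.cdna_hgvs
            if rec.protein_hgvs:
                site.info[protein_field] = rec.protein_hgvs
            gaf = rec.frequencies.global_af
            if gaf is not None and not isinstance(gaf, _Absent):
                site.info[fmap.global_key] = (gaf,)
            for code, key in fmap.subpop_keys.items():
                af = rec.frequencies.subpop_afs.get(code)
                if af is not None and not isinstance(af, _Absent):
                    site.info[key] = (af,)
            out.write(site)
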