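# cpclassify

A gene-aware extension of the five ACMG variant-classification categories,
with chronic pancreatitis (CP) as the bundled worked example.

## The problem

The ACMG five-tier scale (pathogenic, likely pathogenic, VUS, likely benign,
benign) was designed for Mendelian disease genes and forces every variant into
a causal-versus-benign dichotomy. Many diseases — CP among them — span a
continuum from monogenic to multifactorial, and their genes do not contribute
equally: a severe *PRSS1* or *SPINK1* allele can cause CP on its own, whereas
even a complete loss-of-function allele of *CFTR* or *CTRC* only raises risk.

`cpclassify` implements a two-step framework for clinical geneticists and
variant curators:

1. **Gene-level role.** Each gene is classified as *disease-causing* or
   *disease-predisposing* from converging evidence: the census of very rare
   variants (hspAF < 0.001 in every gnomAD subpopulation) found in
   Mendelian-form (hereditary CP) pedigrees — the decisive criterion — plus
   pLoF constraint (gnomAD o/e), aggregate odds ratios, and human knockout
   phenotypes as supporting lines.
2. **Variant-level category.**
   - *Predisposing genes* use a **five-category** scale: predisposing, likely
     predisposing, VUS, likely benign, benign. Legacy
     pathogenic/likely-pathogenic calls are remapped to
     predisposing/likely-predisposing.
   - *Causing genes* use a **seven-category** scale in which two thresholds
     separate pathogenic from predisposing variants:
     an **allele-frequency threshold** (pathogenic requires
     hspAF < 10⁻³) and a **gene-specific functional threshold**
     (for a LoF gene such as *SPINK1*, functional loss ≥ 95 % is pathogenic
     and loss in (10 %, 95 %) is predisposing; for a GoF/GoP gene such as
     *PRSS1*, an experimentally demonstrated gain-of-function or
     gain-of-proteotoxicity effect qualifies). Protective LoF alleles are
     benign with a protective qualifier, and protective promoter alleles can
     be re-expressed as their risk orientation (c.-204C>A → c.-204A>C).

The 0.001 threshold is calibrated against a 47-variant "gold-standard" set of
maximal-confidence pathogenic alleles: only 9/47 (19 %) appear in gnomAD at
all, and after excluding the one outlier (*SPINK1* p.Arg67His, hspAF 0.03078)
the highest hspAF is 0.0007018 (*PRSS1* p.Arg116Cys). Under Hardy–Weinberg
the cutoff corresponds to a carrier frequency < 2·10⁻³ ≈ 667× the hereditary
CP prevalence (0.3/100 000), i.e. it is very conservative for a dominant
disease.

All evidence tables (gene facts, hereditary-pedigree variants, the
gold-standard sets, reclassification inputs, annotation examples) ship as
checksummed TSV/JSON fixtures with a provenance sidecar; the package performs
no live database queries.

## Worked example

```console
$ cpclassify audit-goldstandard
gold-standard variants: 47
present in population data: 9/47 (19%)
outlier (hspAF >= 0.001): SPINK1:c.200G>A hspAF 0.03078
max hspAF after outlier exclusion: 0.0007018 (PRSS1:c.346C>T)

$ cpclassify classify-genes | head -6
CFTR: predisposing (decisive criterion: very_rare_mendelian_census)
  [very_rare_mendelian_census] supports_predisposing: no very rare variant reported from a Mendelian-form pedigree
  [plof_constraint_oe] supports_predisposing: o/e 1.09 > 1 indicates no LoF intolerance
  [aggregate_odds_ratio] supports_predisposing: aggregate OR 2.7 vs threshold 10
  [knockout_phenotype] neutral: no human knockout reported
CTRC: predisposing (decisive criterion: very_rare_mendelian_census)

$ cpclassify freq-ratio --af 0.001 --prevalence 0.3e-5
carrier frequency: 0.002
carrier/prevalence ratio: 666.67

$ cpclassify odds-ratio 20 80 5 95
OR 4.75 (95% CI 1.706-13.23)
```

The audit reproduces the calibration of the frequency threshold: 47
gold-standard variants, 9 observed in population data, one outlier excluded,
maximum remaining hspAF 0.0007018 — comfortably below the 0.001 cutoff. The
ratio 666.67 is the carrier-frequency bound (2 × 0.001) divided by the
hereditary-CP prevalence, the margin that justifies calling the cutoff
conservative. The odds-ratio command returns the Woolf estimate with its
95 % log-normal interval from four 2×2 counts.

From Python, classifying one variant:

```python
from cpclassify.knowledgebase import load_gene_configs, load_reclassification_set
from cpclassify.varclass import build_annotation, classify_variant

configs = load_gene_configs()
records = {r.key: r for r in load_reclassification_set()}
rec = records["SPINK1:c.194G>A"]            # p.Arg65Gln, ~50% functional loss
res = classify_variant(rec, configs["SPINK1"])
print(res.category.value)                   # predisposing
print(build_annotation(res, rec))           # Predisposing (causes a ~50% functional loss of SPINK1)
print(res.fired_rules)                      # ('role-check', '7C-4-predisposing')
```

The variant is very rare, but its ~50 % functional loss sits inside the
predisposing band (10–95 %), below the ≥ 95 % bar that pathogenicity in a
loss-of-function gene requires — so a legacy "pathogenic" call becomes
"predisposing", with the evaluation trail recorded in `fired_rules`.

## Layout

- `cpclassify.types` — domain types and their invariants
- `cpclassify.knowledgebase` — packaged tables, subtype predicates,
  synthetic-variant generator
- `cpclassify.popfreq` — hspAF, the very-rare predicate, carrier/prevalence
  arithmetic, the gold-standard audit
- `cpclassify.generank` — gene-level causing/predisposing classifier
- `cpclassify.varclass` — the variant rule engine, legacy remapping,
  orientation flips, annotation strings
- `cpclassify.stats` — Woolf odds ratios with confidence intervals
- `cpclassify.io` / `cpclassify.cli` — TSV/VCF readers and writers, CLI

See `docs/methods.md` for the model, thresholds and design choices.
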