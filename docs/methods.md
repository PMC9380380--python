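# Methods

## Model

`cpclassify` operationalises a two-level classification framework for
variants in genes related to a disease that spans the monogenic–multifactorial
continuum. Chronic pancreatitis (CP) and its four canonical genes (*PRSS1*,
*SPINK1*, *CFTR*, *CTRC*) are the bundled instantiation, but every threshold
and mechanism set is per-gene configuration, not hard-coded biology.

**Gene level.** A gene is *disease-causing* when at least one high-confidence
variant has been found in the Mendelian form of the disease: a very rare
allele (see below) of the gene's expected mechanism segregating in a
hereditary pedigree (for CP: ≥ 3 affected members over ≥ 2 generations).
This census is decisive. Three further criteria are recorded as supporting
lines with configurable thresholds:

| criterion | supports causing | supports predisposing | default |
|---|---|---|---|
| pLoF constraint (gnomAD o/e) | o/e < 0.5 | o/e > 1.0 | inapplicable for GoF/GoP-mechanism genes |
| aggregate odds ratio | OR ≥ 10 | OR < 10 | threshold 10 |
| human knockout phenotype | severe, early-onset | mild/late or none | — |

The o/e split (0.5 / 1.0) and the OR threshold of 10 were chosen to separate
the observed four-gene values (o/e 0.24 vs 1.09–1.31; OR 15.6 vs 2.7–5.3)
with maximal margin; both are policy parameters. When two or more secondary
criteria oppose the census, the decision carries a warning flag but is not
overturned — the premise of the framework is precisely that a confidently
disease-causing variant in a Mendelian pedigree settles the question. A gene
with no usable evidence is `unassigned` and cannot be used for variant
classification.

**Variant level.** Variants in a predisposing gene use a five-category scale
(predisposing, likely predisposing, VUS, likely benign, benign): every
pathologically relevant variant is predisposing (a legacy "likely pathogenic"
becomes "likely predisposing"), and pathogenic/likely-pathogenic are
unrepresentable by construction. Variants in a causing gene use a
seven-category scale evaluated as a fixed, first-match-wins ladder (rule ids
in parentheses):

1. protective LoF → benign, flagged protective (`7C-1-protective`);
2. pathogenic: hspAF strictly below the gene's frequency threshold AND full
   functional qualification (`7C-2-pathogenic`) — for GoF/GoP genes an
   experimental qualifying assay with a complete panel; for LoF genes
   loss ≥ `pathogenic_min_loss` demonstrated experimentally or presumed
   complete (pLoF);
3. likely pathogenic: very rare with partial support (`7C-3`) — an
   experimental gain-type assay with an incomplete panel (e.g. moderate
   secretion impact, ER stress untested), or a predicted-only complete loss;
4. predisposing: pathologically relevant AND (hspAF ≥ threshold OR loss in
   the open band (`predisposing_min_loss`, `pathogenic_min_loss`)) (`7C-4`);
5. likely predisposing: pathologically relevant with suggestive,
   non-experimental evidence only (`7C-5`);
6. residual (`7C-6`): experimentally neutral → benign; predicted neutral →
   likely benign; a benign-side legacy call is honoured; otherwise VUS.

Every consulted rule is recorded (`fired_rules` and full `RuleTrace`
snapshots), so a category is always auditable.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `af_threshold` | hspAF above which a variant is too common to be pathogenic | 0.001 | the filtering frequency recommended for dominant Mendelian disorders; validated by the gold-standard audit (post-exclusion max hspAF 0.0007018) and by the carrier/prevalence argument (2·0.001 / 3·10⁻⁶ ≈ 667) |
| `pathogenic_min_loss` | minimum functional loss for pathogenicity in a LoF gene | 0.95 | "complete or almost complete (> 95 %)" loss; the boundary is **inclusive** (≥ 0.95), reading "almost complete" as reaching the bar |
| `predisposing_min_loss` | lower bound of the predisposing loss band | 0.10 | "at least 10 %" read as an **open** lower bound (> 0.10) |
| `qualifying_mechanisms_for_pathogenic` | mechanisms that can make a variant pathogenic in this gene | per gene | {GoF, GoP} for *PRSS1*, {LoF} for *SPINK1* |

Frequency semantics: the very-rare predicate compares the *highest
subpopulation* allele frequency (hspAF) against the threshold with a strict
`<`; a variant absent from the reference population is very rare by
definition. Observed-absent (`Absent` in the tables) is distinct from
missing data: a pathologically relevant variant with *no* frequency
information degrades to VUS with an explicit "insufficient frequency data"
trace rather than raising, because curated clinical tables routinely have
gaps. The gold-standard audit flags as outliers the records with
hspAF ≥ threshold — the weakest rule that reproduces the documented
exclusion of *SPINK1* p.Arg67His — and reports the maximum hspAF among the
remaining records. Carrier frequency defaults to the 2p upper bound (the
form used in the published arithmetic); exact Hardy–Weinberg 2p(1−p) is
available as an option.

## Odds ratios

`stats.odds_ratio_ci` computes the Woolf estimate OR = ad/bc with the
log-normal interval exp(ln OR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d)), applying the
Haldane–Anscombe +0.5 correction to all cells iff any cell is zero (flagged
in the result). Exact conditional intervals are out of scope; the aggregate
ORs used in gene classification come from published cohort reports and are
stored as fixture values, not recomputed (the underlying counts are not
available).

## Design choices where the design was open

- **"MAF < 0.001 in any subpopulation"** is read universally (below the
  threshold in *every* subpopulation, i.e. hspAF < 0.001). The existential
  reading would misclassify alleles the framework itself treats as very rare
  (p.Arg116Cys, hspAF 0.0007018).
- **"Likely predisposing"** has no published operational definition; it is
  defined here as pathologically relevant with only non-experimental support.
  This is an extension and is marked as such.
- **Risk-orientation flips.** A protective allele at a biallelic
  substitution site can be re-expressed as its risk allele: HGVS ref/alt
  swapped, every numeric frequency complemented (1 − af, rounded at 12
  decimals so the flip is an involution), and the protective-LoF mechanism
  exchanged with GoF — a promoter allele that protects by lowering expression
  is, in the risk orientation, a gain-of-expression allele. Quantitative
  loss fractions do not survive a flip (they are orientation-specific) and
  are cleared.
- **The twice-printed hybrid allele.** The source gold-standard GoF table
  lists the *PRSS1-PRSS2* hybrid twice; both rows are retained as distinct
  records (`hybrid_1`/`hybrid_2`), which is the only reading under which the
  combined gold-standard census is 47 with 9 present — the documented
  fractions (19 %) depend on it.
- **Clinical subtypes.** HCP uses inclusive bounds (≥ 3 affected, ≥ 2
  generations); pedigree evidence takes precedence over the alcohol flag; an
  external factor other than alcohol excludes idiopathic disease but has no
  subtype of its own, so it raises a validation error instead of guessing.
- **Compound genotypes are out of scope.** Variants are classified
  individually; trans-heterozygous or recessive combinations that might cause
  disease in a predisposing gene are recorded as context notes, never as
  role or category changes.

## Synthetic data

The generator (`knowledgebase.synthetic`) emulates the study conditions of
the bundled tables across three synthetic gene contexts: a GoF/GoP-mechanism
causing gene, a LoF-mechanism causing gene, and a predisposing gene (equal
mixture by default). For each record it first draws a target category, then
samples frequencies and loss fractions inside the corresponding region of
rule space, keeping at least ε = 10⁻⁶ from every decision boundary (the
sampling margins are in fact ≥ 10⁻⁴, and all values are rounded to the 6
significant digits the interchange format carries, which cannot cross a
boundary at that margin). Very rare alleles are log-uniform below the
threshold or observed-absent with probability 0.3, mirroring the
predominantly gnomAD-absent gold-standard set; common risk alleles are
log-uniform between the threshold and 0.1; band losses are uniform.

Because categories are assigned by construction, exact recovery by the rule
engine is a meaningful oracle: it exercises every rule of the ladder, both
systems, and the frequency/loss boundary logic. What it does **not** show is
robustness to real-data pathologies — conflicting assays, frequencies
straddling thresholds within measurement error, miscurated relevance flags —
which is why the worked reclassifications from the curated tables are tested
separately, including the deliberately awkward cases (a common "pathogenic"
allele, a synonymous variant with no frequency data, protective alleles, an
orientation flip). Boundary behaviour itself is tested with hand-placed
values, never with sampled ones.

## Numerical conventions

- TSV output renders floats with 6 significant digits (preserves printed
  gnomAD values such as 0.0007018 exactly); VCF round-trips restore
   6-significant-digit values after htslib's single-precision storage.
- Rule evaluation order is fixed and published; first match wins; ties are
  impossible by construction.
- All randomness flows through a single seeded `numpy` generator; identical
  seeds give byte-identical outputs.

## Problem sizes

The synthetic oracle runs on 1000 variants per seed (three seeds in the test
suite); the odds-ratio closed form is cross-checked on 10⁴ random tables
against an independent re-derivation (tolerance 10⁻¹² relative) and against
`statsmodels` on spot values. The whole suite completes in a few seconds on
one CPU.

## Known limitations

- Gain-type effects are not quantifiable on the loss-fraction scale, so the
  pathogenic bar for GoF/GoP genes is qualitative (experimental demonstration
  with a complete panel); "complete panel" is encoded via assay flags and is
  only as good as the curation.
- No popmax-with-confidence filtering: frequencies are point estimates, as in
  the source tables.
- "Pathologically relevant" is a curator-asserted input flag, not derived.
- Penetrance is not modelled; the ACMG evidence-code combining algebra
  (PVS/PS/PM/…) is out of scope — legacy categories are accepted as inputs.
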