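# Methods

## Scope and design

`paroxscore` reimplements a candidate-gene discovery analysis for cyclic
vomiting syndrome (CVS) as a reusable pipeline. The unit of analysis is
one participant × variant record carrying laboratory annotations
(consequence, population allele frequencies, conservation scores, ClinVar
interpretations, zygosity, and — for mitochondrial records — heteroplasmy).
The pipeline derives per-record categories, per-gene point scores and
evidence tiers, a composite candidate list against literature evidence,
and cohort-level statistics. Because the underlying per-participant cohort
data are not publicly deposited, the package ships (a) per-occurrence
fixtures transcribed from the published variant tables, on which the
scoring is exact, and (b) a seeded generator of synthetic cohorts with the
same statistical structure, on which the distributional properties are
tested.

Coordinates are never interpreted: `variant_id` is an opaque key. No
liftover, HGVS normalization, or annotation computation is performed —
frequencies and conservation scores are inputs, matching the practice of
working from laboratory annotation exports rather than raw VCF semantics.
VCF ingestion is provided as a convenience mapping of documented INFO keys
with genotype-derived zygosity.

## Qualification rules (nuclear)

With thresholds `QualificationThresholds` (defaults in parentheses):

- **Recording**: comparison-population allele frequency strictly below
  `af_record_max` (0.10). A variant absent from the reference is treated
  as frequency 0: absence from a large population database is the
  strongest available rarity evidence.
- **Qualifying** = coding ∧ rare ∧ conserved:
  - *coding*: consequence in {missense, nonsense, frameshift, in-frame
    indel}, or a splice score strictly above `splice_min` (0.6);
  - *rare*: frequency strictly below `af_qualify_max` (0.02);
  - *conserved*: PhyloP ≥ `phylop_min` (1.5), or mammalian alignment
    match ≥ `mammal_match_min_pct` (90).
  Frequency comparisons are strict, conservation inclusive, splice
  strict — matching the operators with which the rules are stated.
- **P/LP**: at least half of the ClinVar interpretations are P or LP
  (ties count as P/LP), or loss of function is highly predicted from the
  protein effect (nonsense, frameshift, large deletion). No further ACMG
  criteria and no in-silico predictor aggregation are applied.
- **Clinical**: the carrier's non-CVS paroxysmal diagnoses intersect the
  gene's associated phenotype set. CVS itself is excluded from both sides
  to avoid a circular argument.
- **Key** = Qualifying ∧ (P/LP ∨ Clinical); **Other** = Qualifying and
  neither.

Repeat-expansion and structural records have no allele-frequency rule;
they qualify exactly when flagged `coding_equivalent`, and such flagged
records are recorded by definition so the nesting key ⊆ qualifying ⊆
recorded holds on every input.

Occurrence collapsing: records of one participant and gene sharing an
explicit `coseg_group` tag count once ("closely spaced variants with
identical prevalence data"); groups are never inferred from positions
because no distance threshold is defined. A group is recorded/qualifying
if any member is, and Key if any member carries P/LP or Clinical
evidence. A homozygous record is one occurrence; hemizygous genotypes
count as heterozygous (the single-copy equivalent for X-linked genes).
Participants with ≥ 2 qualifying occurrence groups in one gene are
reported as phase-unknown recessive candidates; no metabolic-function
filtering is applied (that judgment is downstream).

## Mitochondrial rules

Heteroplasmy strictly below 20% excludes a record as likely recent
somatic origin; exclusion is absorbing. P/LP holds for heteroplasmy in
[40, 98] (both ends inclusive, per the stated range), for a ClinVar P/LP
call, or for a secondary-structure conservation exception
(near-universal Watson–Crick stem binding across mammals). The exception
is an input flag, not computed: tRNA secondary-structure prediction is out
of scope. Heteroplasmy above 98 is effectively homoplasmic and does not
trigger the band; homoplasmic records reach P/LP only via ClinVar or the
structure flag — consistent with the homoplasmic Key entries in the
transcribed table, which are Key via domains or ClinVar. Clinical holds
with mitochondrial findings in ≥ 4 of the eight domains (neuromuscular,
neurodevelopmental, neuropsychiatric, functional, endocrine,
immunological, metabolic, enzymological; the enzymological domain is
complex I or IV activity strictly below 30% of control). Because only
domain *counts* were published, classification accepts counts keyed by
record as well as per-participant domain label sets. All mitochondrial
results pool into the reserved single gene `mtDNA` (mtDNA genes have
highly overlapping phenotypes; the pooled fixture scores 10×3 + 5 = 35
points, top tier).

## Scoring and tiers

`study_points = 3·key_occurrences + other_occurrences`; an occurrence that
is both P/LP and Clinical earns 3 points once. Literature points equal
the number of reported families with paroxysmal vomiting (one per family,
regardless of family size). Tier thresholds: ≥ 12 highly likely, 6–11
likely, 3–5 possibly, ≤ 2 no evidence; the composite tier is the maximum
of the study and literature tiers. The candidate list contains every gene
with composite tier ≥ likely, ordered by study points descending, then
symbol. Genes absent from the published literature table carry zero
families; since only genes reaching ≥ 6 families are published, this
cannot add or remove candidates. Clinician-driven promotions of
non-paroxysmal genes to "Possibly" status involve judgment not reducible
to a rule and are represented as data, not computed.

## Statistics

- **Fisher exact test**: two-tailed by the minimum-likelihood convention
  (the p-value sums point probabilities ≤ that of the observed table over
  fixed margins), the convention of common statistical tools; the
  alternative doubling convention is not used. The implementation is
  scipy's; tests verify it against an independent exhaustive
  hypergeometric enumeration with rational arithmetic on every 2×2 table
  with grand total ≤ 40 at 1e-12. The reported odds ratio is the sample
  cross-product ratio ad/bc (infinite when bc = 0 with ad > 0).
- **Hardy–Weinberg**: carrier frequency 1 − (1 − q)², strictly increasing
  with fixed points only at 0 and 1. The 10% recording cutoff corresponds
  to 19% carriers and the 2% qualifying cutoff to 3.96%.
- **Recurrent-variant tests**: recorded variants carried by ≥ 3
  participants are tested against supplied population allele counts
  (never fetched). Allele counting: 2 per homozygote, 1 per heterozygote
  or hemizygote, denominator 2 alleles per participant.
- **Recorded-variant categorization**: recorded records partition
  exhaustively into non-coding, uncommon coding (2–10%), rare
  lesser-conserved coding, and rare highly-conserved coding.
- **Panel burden comparison**: Fisher on participants with/without ≥ 1
  hit per panel. The published analysis mentions a correction for unequal
  panel sizes without specifying it; `gene_count_rescale` (the larger
  panel's hit count rescaled by the gene-count ratio, rounded half away
  from zero) is offered as a labelled, documented choice, and the
  uncorrected test is always reported alongside — transparency over
  guessing intent.
- **Mixed-population frequency**: weighted average of per-population
  frequencies (weights sum to 1), with a companion helper producing
  mixture allele counts for contingency construction.

Not reproduced, by design: the published p = 0.04 gene-tier comparison,
the opiate-receptor odds ratio and confidence interval, and the
re-analysis p-values of the earlier receptor-SNP study — their
contingency constructions are not stated and the printed values are
internally inconsistent with the printed counts. The operations compute
from supplied inputs and do not target those numbers. Participant-level
union counts (e.g. carriers of ≥ 1 Key variant) are reported with
explicit denominators but are not an acceptance surface, since the
published participant counts disagree internally (31 vs 27 of 80).

## Transcribed fixtures

The nuclear occurrence fixture has one row per variant occurrence per
participant (116 rows across the 35-gene panel) with the transcribed
Key/Other label, zygosity, co-segregation group, P/LP basis, and — for
Clinical variants — a short code for the matched condition. Scoring this
table reproduces the entire published points column, all 35 genes
including zeros, and the 6 + 6 top-tier counts. Replaying the fixture
through the qualification rules (reconstructing annotations that satisfy
the predicates and giving carriers their matched diagnoses) reproduces
every label except one: a participant carries both a Clinical Key variant
and a second qualifying variant in the same gene, and a participant-level
phenotype-match rule necessarily marks both Key where the original
per-variant clinician judgment kept one as Other. The tests pin down
exactly this one divergence. The mitochondrial fixture (15 records, one
unnumbered deletion carrier under the reserved id `P_UNNUMBERED`)
reproduces the 10 Key / 6 P/LP / 5 Other decomposition exactly.

Fixtures are stored in a canonical serialized layout; re-serializing the
parsed tables is byte-identical to the shipped files, guarding against
hand edits that bypass the canonical writer.

## Synthetic cohorts

The generator draws, per participant and panel gene, a qualifying
occurrence with configurable probability (default 0.04, matching the
observed ~120 qualifying occurrences across 80 participants and 35
genes); a Key fraction of 0.26 (≈ 31 of 119) of which 0.32 (≈ 10 of 31)
are P/LP-based, the rest Clinical-based (expressed by giving the carrier
a matching diagnosis; synthetic panels carry one distinct phenotype code
per gene so matches never leak across genes). Rare allele frequencies are
log-normal (ln-scale mean −8, sd 1.5) truncated below the 2% cutoff;
conservation scores come from a two-component normal mixture. Non-coding
background records are added below the recording threshold at rate 0.3,
and mitochondrial records at 0.2 per participant with configurable
heteroplasmy and domain-count distributions. The random stream is split
per (participant, gene) from one seed, so adding a gene never perturbs
another gene's draws, and fixed seeds give byte-identical output tables.

What the generator does not emulate: linkage and co-segregation,
sequencing error, genome coordinates, realistic per-gene mutational
target sizes, and ancestry structure. Passing distributional tests on
synthetic cohorts therefore demonstrates the correctness and calibration
of the *rules and statistics*, not the biological realism of any
particular cohort.

## Problem sizes and numerical choices

The exhaustive Fisher validation deduplicates tables by their row/column/
transpose symmetry before enumeration. The null calibration of the panel
comparison uses 2,000 seeded replicates of two 10-gene panels over 80
participants (type-I error ≤ 0.06 at nominal 0.05); parameter recovery
uses 500 participants × 10 genes with a 4-standard-deviation band per
gene. Percentages in reports are rounded to the nearest integer, half
away from zero. Degenerate inputs: empty cohorts produce empty (all-zero)
reports; a zero-margin contingency table is rejected at construction;
p-values are clamped to at most 1.

## Known limitations

- The Clinical rule is participant-level; per-variant clinician judgment
  within one gene and participant cannot be represented (one documented
  divergence in the fixture replay, above).
- Literature family counts are packaged static data; no literature mining.
- The gene-count correction for unequal panels is a documented
  convention, not a reconstruction of the original (unstated) procedure.
- MitoMap lookups, haplogroup analysis, CNV calling, and any clinical
  judgment beyond the encoded flags are out of scope.
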