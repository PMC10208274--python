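# paroxscore

Rare-variant qualification and candidate-gene scoring for cyclic vomiting
syndrome (CVS) cohorts.

CVS is an idiopathic migraine variant defined by stereotypical, discrete
episodes of nausea and vomiting. `paroxscore` implements a candidate-gene
discovery analysis for sequenced CVS cohorts: per-variant qualification
rules, gene-level point scoring with evidence tiers, adapted rules for
mitochondrial DNA, composite scoring against literature evidence, and the
cohort-level statistics — together with transcribed study fixtures and a
seeded synthetic-cohort generator so every stage is testable without any
external download.

## The scoring model

For each participant × variant record in a gene panel, with allele
frequency *q* in the comparison population (Non-Finnish Europeans by
default; absence from gnomAD counts as *q* = 0):

- **Recorded**: *q* < 0.10. Under Hardy–Weinberg equilibrium the carrier
  frequency is 1 − (1 − *q*)², so this excludes variants carried by over
  19% of the population.
- **Qualifying**: coding (missense / nonsense / frameshift / in-frame
  indel, or splice score > 0.6 on SpliceRF or SpliceADA), rare
  (*q* < 0.02, i.e. carriers ≲ 4%), and conserved (PhyloP ≥ 1.5 or a
  match in ≥ 90% of aligned mammalian species).
- **Key Qualifying**: a Qualifying variant that is additionally **P/LP**
  (at least half of its ClinVar interpretations are Pathogenic/Likely
  Pathogenic, or loss of function is highly predicted from the protein
  effect) or **Clinical** (its carrier holds a non-CVS paroxysmal
  diagnosis associated with the gene — CVS itself never matches, to avoid
  circularity).

Closely-spaced co-segregating variants collapse to one occurrence, as does
a homozygous genotype. Each Key occurrence earns its gene 3 points, each
Other Qualifying occurrence 1 point; literature evidence earns 1 point per
reported family with paroxysmal vomiting. Points map to tiers —
≥ 12 *Highly likely*, 6–11 *Likely*, 3–5 *Possibly*, ≤ 2 *No evidence* —
and a gene's composite tier is the stronger of its study and literature
tiers. Mitochondrial variants follow adapted rules (heteroplasmy < 20%
excluded as likely somatic; 40–98% counts as P/LP, as do ClinVar calls and
secondary-structure conservation exceptions; Clinical requires findings in
≥ 4 of 8 symptom domains) and pool into a single `mtDNA` gene.

## Worked example

Scoring the packaged study fixtures (the transcribed per-occurrence
variant tables of an 80-participant CVS cohort):

```
$ python analysis/01_score_paroxysmal_panel.py
highly_likely (6 genes): SCN4A (20), CACNA1A (19), CACNA1S (17), RYR2 (15), TRAP1 (14), MEFV (12)
likely (6 genes): TNFRSF1A (10), SCN10A (9), POLG (9), SCN9A (8), TRPA1 (7), POGZ (7)

$ python analysis/02_classify_mtdna.py
15 mtDNA records: 10 Key (6 also P/LP), 5 Other, 0 excluded
pooled mtDNA score: 35 points -> highly_likely

$ python analysis/03_build_candidate_list.py
22 candidate genes (composite tier >= likely):
  mtDNA      study  35 (highly_likely), literature   0 (no_evidence) -> highly_likely
  SCN4A      study  20 (highly_likely), literature   0 (no_evidence) -> highly_likely
  ...
```

SCN4A's 20 points mean 4 Key occurrences (3 points each) plus 8 Other
occurrences across the cohort; the 22-gene candidate list joins the 12
genes supported by the study cohort, 9 genes supported by the literature
alone (e.g. OTC with 54 reported families), and the pooled mtDNA.

The numbered scripts under `analysis/` write their tables to `results/`:
gene scores, the mtDNA classification, the candidate list, the panel
burden statistics (`04`), and a seeded synthetic-cohort validation (`05`).
The same stages are available as a CLI (`paroxscore run|qualify|mtdna|
score|stats|simulate|fixtures`) and as library functions
(`paroxscore.qualify_cohort`, `classify_mito`, `score_gene`, ...).

## Layout

```
src/paroxscore/      library: models, io, fixtures, qualification, mtdna,
                     scoring, stats, simulate, pipeline, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      model assumptions, parameters, numerical choices
```
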