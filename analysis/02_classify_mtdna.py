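#!/usr/bin/env python
"""Classify the 15 transcribed mitochondrial variant records: exclude
likely-somatic low heteroplasmy, then apply the P/LP band (40-98%),
ClinVar and structure-exception flags, and the >= 4 clinical-domain rule.

Writes results/mtdna_classification.tsv and prints the Key / P/LP / Other
decomposition and the pooled mtDNA gene score.
"""

import csv
from pathlib import Path

from paroxscore.fixtures import mtdna_fixture_as_variants, mtdna_fixture_domain_counts
from paroxscore.models import MitoCategory
from paroxscore.mtdna import classify_mito
from paroxscore.scoring import score_mtdna

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    classes = classify_mito(
        mtdna_fixture_as_variants(), domain_counts=mtdna_fixture_domain_counts()
    )
    OUT.mkdir(exist_ok=True)
    with open(OUT / "mtdna_classification.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "variant_id", "participant_id", "plp", "clinical", "category"])
        for c in classes:
            writer.writerow(
                [c.variant.gene, c.variant.variant_id, c.variant.participant_id,
                 int(c.plp), int(c.clinical), c.category.value]
            )

    key = [c for c in classes if c.category is MitoCategory.KEY]
    other = [c for c in classes if c.category is MitoCategory.OTHER]
    score = score_mtdna(classes)
    print(f"{len(classes)} mtDNA records: {len(key)} Key "
          f"({sum(1 for c in key if c.plp)} also P/LP), {len(other)} Other, "
          f"{sum(1 for c in classes if c.excluded_somatic)} excluded")
    print(f"pooled mtDNA score: {score.study_points} points -> {score.study_tier.label}")
    print(f"wrote {OUT / 'mtdna_classification.tsv'}")


if __name__ == "__main__":
    main()
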