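#!/usr/bin/env python
"""Combine study scores, literature family counts, and the pooled mtDNA
score into composite tiers and the final candidate-gene list (every gene
whose composite tier is at least Likely).

Writes results/candidate_genes.tsv and prints the list.
"""

from pathlib import Path

from paroxscore.fixtures import (
    load_fixture,
    mtdna_fixture_as_variants,
    mtdna_fixture_domain_counts,
)
from paroxscore.models import MTDNA_GENE
from paroxscore.mtdna import classify_mito
from paroxscore.scoring import (
    build_candidate_list,
    score_mtdna,
    score_occurrence_table,
    scores_to_frame,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scores = score_occurrence_table(
        load_fixture("table2_occurrences"), load_fixture("paroxysmal_panel")
    )
    lit = load_fixture("literature_points")
    for gene, families in zip(lit["gene"], lit["families"]):
        if gene in scores:
            scores[gene].literature_families = families
    classes = classify_mito(
        mtdna_fixture_as_variants(), domain_counts=mtdna_fixture_domain_counts()
    )
    scores[MTDNA_GENE] = score_mtdna(classes)

    candidates = build_candidate_list(scores)
    frame = scores_to_frame({s.gene: s for s in candidates})
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "candidate_genes.tsv", sep="\t", index=False)

    print(f"{len(candidates)} candidate genes (composite tier >= likely):")
    for s in candidates:
        print(f"  {s.gene:10s} study {s.study_points:3d} ({s.study_tier.label}), "
              f"literature {s.literature_points:3d} ({s.literature_tier.label}) "
              f"-> {s.composite_tier.label}")
    print(f"wrote {OUT / 'candidate_genes.tsv'}")


if __name__ == "__main__":
    main()
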