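#!/usr/bin/env python
"""Score the 35 paroxysmal panel genes from the transcribed study
occurrence table: 3 points per Key Qualifying occurrence, 1 per Other,
co-segregating variants collapsed to one occurrence.

Writes results/gene_scores.tsv and prints the genes reaching the top two
evidence tiers.
"""

from pathlib import Path

from paroxscore.fixtures import load_fixture
from paroxscore.models import Tier
from paroxscore.scoring import score_occurrence_table, scores_to_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    occurrences = load_fixture("table2_occurrences")
    panel = load_fixture("paroxysmal_panel")
    lit = load_fixture("literature_points")
    scores = score_occurrence_table(occurrences, panel)
    for gene, families in zip(lit["gene"], lit["families"]):
        if gene in scores:
            scores[gene].literature_families = families

    frame = scores_to_frame(scores).sort_values(
        ["study_points", "gene"], ascending=[False, True], kind="mergesort"
    )
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "gene_scores.tsv", sep="\t", index=False)

    for tier in (Tier.HIGHLY_LIKELY, Tier.LIKELY):
        genes = [
            f"{s.gene} ({s.study_points})"
            for s in sorted(scores.values(), key=lambda s: -s.study_points)
            if s.study_tier is tier
        ]
        print(f"{tier.label} ({len(genes)} genes): {', '.join(genes)}")
    print(f"wrote {OUT / 'gene_scores.tsv'} ({len(frame)} genes)")


if __name__ == "__main__":
    main()
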