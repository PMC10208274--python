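"""Gene-level point scoring and evidence tiers.

Each Key Qualifying occurrence earns its gene 3 points, each Other
Qualifying occurrence 1 point; an occurrence that is both P/LP and Clinical
still earns 3 points once.  Literature evidence scores one point per family
with reported paroxysmal vomiting.  Points map to tiers:

======== ================
points   tier
======== ================
>= 12    highly_likely
6 - 11   likely
3 - 5    possibly
<= 2     no_evidence
======== ================

The composite tier of a gene is the stronger of its study and literature
tiers.  All mitochondrial occurrences are pooled under the reserved gene
symbol ``mtDNA``.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .models import (
    Category,
    GenePanel,
    GeneScore,
    MITO_DOMAINS,  # noqa: F401  (re-exported for report annotations)
    MTDNA_GENE,
    MitoCategory,
    MitoClassification,
    QualificationResult,
    Tier,
)

KEY_POINTS = 3
OTHER_POINTS = 1

_TIER_FLOORS = [(12, Tier.HIGHLY_LIKELY), (6, Tier.LIKELY), (3, Tier.POSSIBLY)]


def assign_tier(points: int) -> Tier:
    if points < 0:
        raise ValueError(f"points must be non-negative, got {points}")
    for floor, tier in _TIER_FLOORS:
        if points >= floor:
            return tier
    return Tier.NO_EVIDENCE


def composite_tier(study: Tier, literature: Tier) -> Tier:
    return max(study, literature)


def score_gene(
    gene: str,
    results: list[QualificationResult],
    literature_families: int = 0,
) -> GeneScore:
    """Tally one gene's occurrence counts into a :class:`GeneScore`.

    ``results`` must already be occurrence-collapsed (as produced by
    :func:`~paroxscore.qualification.qualify_cohort`).
    """
    for r in results:
        if r.gene != gene:
            raise ValueError(f"result for gene {r.gene!r} passed to score_gene({gene!r})")
    key = sum(1 for r in results if r.category is Category.KEY)
    other = sum(1 for r in results if r.category is Category.OTHER)
    return GeneScore(
        gene=gene,
        key_occurrences=key,
        other_occurrences=other,
        literature_families=literature_families,
    )


def score_panel(
    results: list[QualificationResult],
    panel: GenePanel,
    literature_families: dict[str, int] | None = None,
) -> dict[str, GeneScore]:
    """Score every panel gene (genes without occurrences score zero)."""
    literature_families = literature_families or {}
    by_gene: dict[str, list[QualificationResult]] = defaultdict(list)
    for r in results:
        by_gene[r.gene].append(r)
    return {
        gene: score_gene(gene, by_gene.get(gene, []), literature_families.get(gene, 0))
        for gene in panel.genes
    }


def score_mtdna(
    classifications: list[MitoClassification], literature_families: int = 0
) -> GeneScore:
    """Pool all mitochondrial classifications into the single mtDNA score.

    Excluded records contribute nothing.
    """
    key = sum(1 for c in classifications if c.category is MitoCategory.KEY)
    other = sum(1 for c in classifications if c.category is MitoCategory.OTHER)
    return GeneScore(
        gene=MTDNA_GENE,
        key_occurrences=key,
        other_occurrences=other,
        literature_families=literature_families,
    )


def score_occurrence_table(
    occurrences: pd.DataFrame, panel: GenePanel | None = None
) -> dict[str, GeneScore]:
    """Score a transcribed occurrence table (gene / participant_id /
    category / coseg_group columns) by collapsing co-segregation groups and
    tallying Key and Other occurrences per gene.

    A co-segregation group counts once; its label is Key if any member row
    is labelled Key.  When a panel is given, all panel genes appear in the
    output, zero-scored if absent from the table.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {"key": 0, "other": 0})
    grouped: dict[tuple[str, str, str], list[str]] = defaultdict(list)
    for row in occurrences.itertuples(index=False):
        coseg = getattr(row, "coseg_group", "") or ""
        if coseg:
            grouped[(row.gene, row.participant_id, coseg)].append(row.category)
        else:
            counts[row.gene][row.category] += 1
    for (gene, _pid, _tag), labels in grouped.items():
        label = "key" if "key" in labels else "other"
        counts[gene][label] += 1
    genes = panel.genes if panel is not None else sorted(counts)
    return {
        g: GeneScore(
            gene=g,
            key_occurrences=counts[g]["key"] if g in counts else 0,
            other_occurrences=counts[g]["other"] if g in counts else 0,
        )
        for g in genes
    }


def build_candidate_list(scores: dict[str, GeneScore]) -> list[GeneScore]:
    """Genes whose composite tier is at least Likely, ordered by study
    points (descending) then gene symbol."""
    selected = [s for s in scores.values() if s.composite_tier >= Tier.LIKELY]
    return sorted(selected, key=lambda s: (-s.study_points, s.gene))


def scores_to_frame(scores: dict[str, GeneScore]) -> pd.DataFrame:
    """Gene scores as the report table (one row per gene)."""
    rows = [
        {
            "gene": s.gene,
            "key_occurrences": s.key_occurrences,
            "other_occurrences": s.other_occurrences,
            "study_points": s.study_points,
            "study_tier": s.study_tier.label,
            "literature_points": s.literature_points,
            "literature_tier": s.literature_tier.label,
            "composite_tier": s.composite_tier.label,
        }
        for s in scores.values()
    ]
    return pd.DataFrame(rows)
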