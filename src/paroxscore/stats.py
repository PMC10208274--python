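"""Cohort-level statistics.

Exact two-tailed Fisher tests (minimum-likelihood convention: the p-value
sums the point probabilities of all tables with the observed margins that
are no more probable than the observed table), Hardy-Weinberg carrier
conversion, recurrent-variant enrichment against population allele counts,
the four-way categorization of recorded variants, mixed-population
frequency construction, and the paroxysmal-vs-control panel burden
comparison.

Population allele counts are always inputs (a table or config); nothing is
fetched, pinning the analysis to a fixed reference release.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

from scipy import stats as sps

from .models import (
    AnnotatedVariant,
    Category,
    Contingency2x2,
    FisherResult,
    QualificationResult,
    QualificationThresholds,
    ValidationError,
    Zygosity,
)
from .qualification import is_coding, is_conserved

RECURRENCE_MIN_PARTICIPANTS = 3

#: Alleles contributed to a cohort count by one carrier.
_ALLELES_PER_ZYGOSITY = {Zygosity.HET: 1, Zygosity.HEMI: 1, Zygosity.HOM: 2}


def fisher_exact(table: Contingency2x2) -> FisherResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    The odds ratio is the sample odds ratio a*d / b*c (infinite when
    b*c = 0 with a*d > 0, NaN when both products vanish).
    """
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return FisherResult(p_two_tailed=min(float(p), 1.0), odds_ratio=odds, table=table)


def carrier_frequency(q: float) -> float:
    """Hardy-Weinberg carrier frequency 1 - (1 - q)^2 for allele frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"allele frequency out of [0, 1]: {q}")
    return 1.0 - (1.0 - q) ** 2


def allele_frequency_for_carrier(c: float) -> float:
    """Inverse of :func:`carrier_frequency`: q = 1 - sqrt(1 - c)."""
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"carrier frequency out of [0, 1]: {c}")
    return 1.0 - math.sqrt(1.0 - c)


@dataclass
class PopulationAlleles:
    """Reference allele counts for one variant in one population."""

    variant_id: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValidationError(
                f"{self.variant_id}: allele_count {self.allele_count} out of "
                f"[0, {self.allele_number}]"
            )


def recurrent_variant_tests(
    results: list[QualificationResult],
    population_alleles: dict[str, PopulationAlleles],
    n_participants: int,
    min_participants: int = RECURRENCE_MIN_PARTICIPANTS,
) -> dict[str, FisherResult]:
    """Fisher test of cohort vs population allele counts for every recorded
    variant carried by at least ``min_participants`` participants.

    Cohort alleles: 2 per homozygote, 1 per heterozygote or hemizygote;
    the cohort denominator is 2 alleles per participant.
    """
    carriers: dict[str, set[str]] = defaultdict(set)
    alt_alleles: Counter[str] = Counter()
    for r in results:
        if not r.recorded:
            continue
        for v in r.variants:
            carriers[v.variant_id].add(v.participant_id)
            alt_alleles[v.variant_id] += _ALLELES_PER_ZYGOSITY[v.zygosity]
    out = {}
    for variant_id, carrier_set in sorted(carriers.items()):
        if len(carrier_set) < min_participants:
            continue
        if variant_id not in population_alleles:
            raise KeyError(
                f"no population allele counts supplied for tested variant {variant_id!r}"
            )
        pop = population_alleles[variant_id]
        a = alt_alleles[variant_id]
        b = 2 * n_participants - a
        table = Contingency2x2(a=a, b=b, c=pop.allele_count, d=pop.allele_number - pop.allele_count)
        out[variant_id] = fisher_exact(table)
    return out


RECORDED_CLASSES = (
    "non_coding",
    "coding_2_10pct",
    "coding_rare_nonconserved",
    "coding_rare_conserved",
)


def categorize_recorded(
    results: list[QualificationResult],
    t: QualificationThresholds | None = None,
) -> dict[str, int]:
    """Partition recorded variant records into the four exhaustive classes:
    non-coding; uncommon coding (frequency 2-10%); rare lesser-conserved
    coding; rare highly-conserved coding."""
    t = t or QualificationThresholds()
    counts = dict.fromkeys(RECORDED_CLASSES, 0)
    for r in results:
        if not r.recorded:
            continue
        for v in r.variants:
            counts[_recorded_class(v, t)] += 1
    return counts


def _recorded_class(v: AnnotatedVariant, t: QualificationThresholds) -> str:
    if not is_coding(v, t):
        return "non_coding"
    if v.frequency(t.comparison_population) >= t.af_qualify_max:
        return "coding_2_10pct"
    if is_conserved(v, t):
        return "coding_rare_conserved"
    return "coding_rare_nonconserved"


def mixed_population_frequency(
    freqs: dict[str, float], weights: dict[str, float]
) -> float:
    """Weighted average allele frequency for a synthetic mixed population
    (weights are ancestry proportions summing to 1)."""
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValidationError(f"population weights must sum to 1, got {sum(weights.values())}")
    missing = set(weights) - set(freqs)
    if missing:
        raise KeyError(f"no frequency supplied for population(s): {sorted(missing)}")
    return sum(weights[pop] * freqs[pop] for pop in weights)


def mixed_population_alleles(
    counts: dict[str, tuple[int, int]], weights: dict[str, float]
) -> tuple[float, float]:
    """Companion helper: (allele_count, allele_number) for the mixture given
    per-population (allele_count, allele_number) pairs.

    Each population's allele number is rescaled to its weight share of the
    total so the mixture matches the target ancestry composition.
    """
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValidationError(f"population weights must sum to 1, got {sum(weights.values())}")
    total = sum(an for _, an in counts.values())
    ac_mix = 0.0
    an_mix = 0.0
    for pop, weight in weights.items():
        ac, an = counts[pop]
        share = weight * total
        ac_mix += share * (ac / an)
        an_mix += share
    return ac_mix, an_mix


def panel_burden_comparison(
    panel_a_hits: int,
    panel_b_hits: int,
    n_a_genes: int,
    n_b_genes: int,
    n_participants: int,
    correction: str = "none",
) -> FisherResult:
    """Compare participants with at least one hit between two gene panels.

    ``correction="gene_count_rescale"`` rescales the larger panel's hit
    count by the gene-count ratio (rounded half away from zero) before
    testing, as a labelled, documented adjustment for unequal panel sizes;
    the applied correction is recorded on the result.
    """
    if correction not in ("none", "gene_count_rescale"):
        raise ValueError(f"unknown correction {correction!r}")
    for name, hits in (("panel_a_hits", panel_a_hits), ("panel_b_hits", panel_b_hits)):
        if not 0 <= hits <= n_participants:
            raise ValidationError(f"{name}={hits} out of [0, {n_participants}]")
    a_hits, b_hits = panel_a_hits, panel_b_hits
    if correction == "gene_count_rescale" and n_a_genes != n_b_genes:
        if n_a_genes > n_b_genes:
            a_hits = _round_half_away(a_hits * n_b_genes / n_a_genes)
        else:
            b_hits = _round_half_away(b_hits * n_a_genes / n_b_genes)
    table = Contingency2x2(
        a=a_hits,
        b=n_participants - a_hits,
        c=b_hits,
        d=n_participants - b_hits,
    )
    result = fisher_exact(table)
    result.correction = correction
    return result


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
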