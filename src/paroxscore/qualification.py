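"""Nuclear variant rules: recording, qualification, and Key/Other categories.

A variant is *recorded* when its comparison-population allele frequency is
below 10%; *Qualifying* when it is coding (amino-acid altering, or carrying
splice-alteration evidence above 0.6), rare (frequency below 2%) and
conserved (PhyloP >= 1.5, or a mammalian alignment match of >= 90%); and
*Key Qualifying* when it is additionally P/LP (ClinVar majority or high
loss-of-function prediction) or *Clinical* (its carrier holds a non-CVS
paroxysmal diagnosis associated with the gene).  Frequency comparisons are
strict, conservation inclusive, splice strict.

Closely-spaced variants with identical population prevalence co-segregate
and count as a single occurrence; groups are never inferred from positions
but always come from an explicit ``coseg_group`` tag.  A homozygous record
is likewise a single occurrence, and hemizygous records count as
heterozygous (the single-copy equivalent for X-linked genes).
"""

from __future__ import annotations

from collections import defaultdict

from .models import (
    AnnotatedVariant,
    Category,
    ClinVarCall,
    CODING_CONSEQUENCES,
    CVS_CODE,
    FLAG_QUALIFIED_CONSEQUENCES,
    GenePanel,
    ParticipantPhenotype,
    QualificationResult,
    QualificationThresholds,
)


def is_coding(variant: AnnotatedVariant, t: QualificationThresholds | None = None) -> bool:
    """True when the variant alters the amino-acid sequence or is a
    predicted splice-altering change (splice score strictly above cutoff)."""
    t = t or QualificationThresholds()
    if variant.consequence in CODING_CONSEQUENCES:
        return True
    for score in (variant.splice_rf, variant.splice_ada):
        if score is not None and score > t.splice_min:
            return True
    return False


def is_recorded(variant: AnnotatedVariant, t: QualificationThresholds | None = None) -> bool:
    """True when the comparison-population frequency is strictly below the
    recording cutoff; a variant absent from gnomAD counts as frequency 0.

    Flag-qualified record types (repeat expansions, structural events) have
    no reference-population frequency rule; when flagged coding-equivalent
    they are recorded by definition, preserving key => qualifying => recorded.
    """
    t = t or QualificationThresholds()
    if variant.consequence in FLAG_QUALIFIED_CONSEQUENCES and variant.coding_equivalent:
        return True
    return variant.frequency(t.comparison_population) < t.af_record_max


def is_conserved(variant: AnnotatedVariant, t: QualificationThresholds | None = None) -> bool:
    t = t or QualificationThresholds()
    if variant.phylop is not None and variant.phylop >= t.phylop_min:
        return True
    if (
        variant.mammal_match_pct is not None
        and variant.mammal_match_pct >= t.mammal_match_min_pct
    ):
        return True
    return False


def is_qualifying(variant: AnnotatedVariant, t: QualificationThresholds | None = None) -> bool:
    """Coding, rare, and conserved.

    Repeat-expansion and structural records have no allele-frequency rule;
    they qualify exactly when flagged ``coding_equivalent``.
    """
    t = t or QualificationThresholds()
    if variant.consequence in FLAG_QUALIFIED_CONSEQUENCES:
        return variant.coding_equivalent
    return (
        is_coding(variant, t)
        and variant.frequency(t.comparison_population) < t.af_qualify_max
        and is_conserved(variant, t)
    )


def aggregate_clinvar(calls: list[ClinVarCall], lof_predicted: bool = False) -> bool:
    """Majority rule for P/LP status.

    True when loss of function is highly predicted from the protein effect,
    or when at least half of the ClinVar interpretations are P or LP.
    An empty call list without LoF prediction is not P/LP.
    """
    if lof_predicted:
        return True
    if not calls:
        return False
    plp = sum(1 for c in calls if c in (ClinVarCall.P, ClinVarCall.LP))
    return plp >= len(calls) / 2


def is_plp(variant: AnnotatedVariant) -> bool:
    return aggregate_clinvar(variant.clinvar_calls, variant.lof_predicted)


def is_clinical(
    variant: AnnotatedVariant,
    participant: ParticipantPhenotype,
    panel: GenePanel,
) -> bool:
    """True when the carrier holds a non-CVS paroxysmal diagnosis among the
    gene's associated phenotypes.  CVS itself never matches."""
    phenotypes = panel.phenotypes(variant.gene) - {CVS_CODE}
    diagnoses = participant.paroxysmal_diagnoses - {CVS_CODE}
    return bool(phenotypes & diagnoses)


def collapse_cosegregating(
    records: list[AnnotatedVariant],
) -> list[list[AnnotatedVariant]]:
    """Group one participant's records in one gene into occurrence groups.

    Records sharing a ``coseg_group`` tag form one occurrence; ungrouped
    records are singletons.  Input order is preserved for determinism.
    """
    if not records:
        return []
    pids = {r.participant_id for r in records}
    genes = {r.gene for r in records}
    if len(pids) > 1 or len(genes) > 1:
        raise ValueError(
            "collapse_cosegregating expects records of one participant and one gene, "
            f"got participants {sorted(pids)} genes {sorted(genes)}"
        )
    groups: dict[str, list[AnnotatedVariant]] = {}
    order: list[str] = []
    for i, record in enumerate(records):
        tag = record.coseg_group if record.coseg_group else f"__singleton_{i}"
        if tag not in groups:
            groups[tag] = []
            order.append(tag)
        groups[tag].append(record)
    return [groups[tag] for tag in order]


def _qualify_group(
    group: list[AnnotatedVariant],
    participant: ParticipantPhenotype,
    panel: GenePanel,
    t: QualificationThresholds,
) -> QualificationResult:
    """Evaluate one occurrence group.

    Key status is evaluated per group: the group is recorded/qualifying if
    any member is, and Key if any member carries P/LP or Clinical evidence.
    """
    recorded = any(is_recorded(v, t) for v in group)
    qualifying = any(is_qualifying(v, t) for v in group)
    plp = qualifying and any(is_plp(v) for v in group)
    clinical = qualifying and any(
        v.gene in panel and is_clinical(v, participant, panel) for v in group
    )
    if not recorded:
        category = Category.NOT_RECORDED
    elif not qualifying:
        category = Category.RECORDED_ONLY
    elif plp or clinical:
        category = Category.KEY
    else:
        category = Category.OTHER
    return QualificationResult(
        participant_id=group[0].participant_id,
        gene=group[0].gene,
        variants=list(group),
        recorded=recorded,
        qualifying=qualifying,
        plp=plp,
        clinical=clinical,
        category=category,
    )


def qualify_cohort(
    variants: list[AnnotatedVariant],
    phenotypes: list[ParticipantPhenotype],
    panel: GenePanel,
    t: QualificationThresholds | None = None,
) -> list[QualificationResult]:
    """Apply the full rule set; one result per occurrence group.

    Results are ordered by (gene, participant, first variant) so a permuted
    input yields the same output.
    """
    t = t or QualificationThresholds()
    by_participant = {p.participant_id: p for p in phenotypes}
    unknown = sorted({v.participant_id for v in variants} - set(by_participant))
    if unknown:
        raise KeyError(
            f"phenotype table does not cover participant id(s): {', '.join(unknown)}"
        )
    buckets: dict[tuple[str, str], list[AnnotatedVariant]] = defaultdict(list)
    for v in sorted(variants, key=lambda v: (v.gene, v.participant_id, v.variant_id)):
        buckets[(v.gene, v.participant_id)].append(v)
    results = []
    for (gene, pid), records in sorted(buckets.items()):
        for group in collapse_cosegregating(records):
            results.append(_qualify_group(group, by_participant[pid], panel, t))
    return results


def detect_recessive_candidates(
    results: list[QualificationResult],
) -> list[tuple[str, str, int]]:
    """Participant x gene pairs with two or more qualifying occurrence
    groups — candidates for recessive (compound heterozygous) disease.

    Phase is unknown from the occurrence data alone; every reported pair
    needs downstream review (parental phasing, metabolic relevance).
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for r in results:
        if r.qualifying:
            counts[(r.participant_id, r.gene)] += 1
    return sorted(
        (pid, gene, n) for (pid, gene), n in counts.items() if n >= 2
    )
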