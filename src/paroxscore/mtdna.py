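"""Mitochondrial variant rules.

The mtDNA differs from nuclear DNA in copy number and inheritance, so the
rules are adapted: records with heteroplasmy (minor allele proportion)
strictly below 20% are excluded as likely recent somatic changes;
heteroplasmy of 40-98% counts as P/LP, as do ClinVar likely-pathogenic
calls and rare secondary-structure conservation exceptions (near-universal
Watson-Crick stem binding across mammals, carried as an input flag).  The
Clinical rule counts mitochondrial clinical findings in four or more of the
eight domains.  For scoring, the whole mtDNA is pooled as a single gene.

Homoplasmic records carry no heteroplasmy value: they are never excluded
and the 40-98 band does not apply to them (heteroplasmy above 98 is treated
as effectively homoplasmic for the same reason).
"""

from __future__ import annotations

from .models import (
    AnnotatedVariant,
    ClinVarCall,
    Genome,
    MITO_DOMAINS,
    MitoCategory,
    MitoClassification,
    ParticipantPhenotype,
    ValidationError,
)

HETEROPLASMY_EXCLUDE_BELOW = 20.0
PLP_BAND = (40.0, 98.0)
CLINICAL_MIN_DOMAINS = 4
COMPLEX_ACTIVITY_MAX_PCT = 30.0


def mito_exclude(heteroplasmy_pct: float | None) -> bool:
    """Exclude likely somatic records: heteroplasmy present and < 20%."""
    if heteroplasmy_pct is None:
        return False
    if not 0.0 <= heteroplasmy_pct <= 100.0:
        raise ValidationError(f"heteroplasmy_pct out of [0, 100]: {heteroplasmy_pct}")
    return heteroplasmy_pct < HETEROPLASMY_EXCLUDE_BELOW


def mito_plp(
    heteroplasmy_pct: float | None,
    clinvar_lp: bool = False,
    structure_exception: bool = False,
) -> bool:
    """P/LP rule: heteroplasmy in the 40-98 band (inclusive), a ClinVar
    P/LP call, or a secondary-structure conservation exception."""
    lo, hi = PLP_BAND
    in_band = heteroplasmy_pct is not None and lo <= heteroplasmy_pct <= hi
    return in_band or clinvar_lp or structure_exception


def mito_clinical(domains: set[str] | int) -> bool:
    """Clinical rule: findings in four or more of the eight domains.

    Accepts either a set of domain labels or a bare count (the published
    records carry only counts).
    """
    if isinstance(domains, int):
        if not 0 <= domains <= len(MITO_DOMAINS):
            raise ValidationError(f"domain count out of range 0-8: {domains}")
        return domains >= CLINICAL_MIN_DOMAINS
    unknown = set(domains) - MITO_DOMAINS
    if unknown:
        raise ValidationError(f"unknown mito domain label(s): {sorted(unknown)}")
    return len(domains) >= CLINICAL_MIN_DOMAINS


def enzymological_domain(
    complex_i_pct: float | None = None, complex_iv_pct: float | None = None
) -> bool:
    """The enzymological domain holds when complex I or IV activity is
    strictly below 30% of control in muscle or buccal cells."""
    for value in (complex_i_pct, complex_iv_pct):
        if value is not None and value < COMPLEX_ACTIVITY_MAX_PCT:
            return True
    return False


def _record_clinvar_lp(variant: AnnotatedVariant) -> bool:
    return any(c in (ClinVarCall.P, ClinVarCall.LP) for c in variant.clinvar_calls)


def classify_mito(
    records: list[AnnotatedVariant],
    phenotypes: list[ParticipantPhenotype] | None = None,
    domain_counts: dict[tuple[str, str], int] | None = None,
) -> list[MitoClassification]:
    """Classify mitochondrial records: exclusion first (absorbing), then
    P/LP and Clinical evidence, then the Key/Other category.

    Domain evidence is taken from ``domain_counts`` (keyed by
    (participant_id, variant_id)) when given, otherwise from the
    participant's ``mito_domains`` phenotype set.
    """
    by_participant = {p.participant_id: p for p in phenotypes or []}
    out = []
    for v in records:
        if v.genome is not Genome.MITOCHONDRIAL:
            raise ValidationError(
                f"classify_mito received a nuclear record: {v.gene} {v.variant_id}"
            )
        excluded = mito_exclude(v.heteroplasmy_pct)
        if excluded:
            out.append(
                MitoClassification(
                    variant=v,
                    excluded_somatic=True,
                    plp=False,
                    clinical=False,
                    category=MitoCategory.EXCLUDED,
                )
            )
            continue
        plp = mito_plp(v.heteroplasmy_pct, _record_clinvar_lp(v), v.structure_exception)
        if domain_counts is not None and (v.participant_id, v.variant_id) in domain_counts:
            clinical = mito_clinical(domain_counts[(v.participant_id, v.variant_id)])
        elif v.participant_id in by_participant:
            clinical = mito_clinical(by_participant[v.participant_id].mito_domains)
        else:
            clinical = False
        category = MitoCategory.KEY if (plp or clinical) else MitoCategory.OTHER
        out.append(
            MitoClassification(
                variant=v,
                excluded_somatic=False,
                plp=plp,
                clinical=clinical,
                category=category,
            )
        )
    return out
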