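"""Packaged study fixtures.

The per-participant variant data behind the published candidate-gene tables
are transcribed here as small TSVs shipped with the package:

``table2_occurrences``
    One row per variant occurrence per participant in the 35 paroxysmal
    genes, with its transcribed Key/Other label, zygosity, co-segregation
    group, P/LP basis and (for Clinical variants) a short code for the
    matched non-CVS paroxysmal condition.
``mtdna_table``
    The 15 mitochondrial variant records with heteroplasmy, clinical-domain
    count, ClinVar likely-pathogenic flag and secondary-structure
    conservation exception flag.  Only domain *counts* were published, so
    ``domain_labels`` is empty and classification uses ``n_domains``.  The
    unnumbered 7.7-kb deletion carrier is stored under the reserved
    participant id ``P_UNNUMBERED``.
``literature_points``
    Per-gene counts of literature families with reported paroxysmal
    vomiting (one point each).  Genes absent from the published table carry
    zero families.
``paroxysmal_panel`` / ``dntr_panel``
    The 35-gene paroxysmal panel (with associated phenotype codes) and the
    20-gene dominant neurotransmitter-receptor control panel.
"""

from __future__ import annotations

import csv
from importlib import resources

import pandas as pd

from .models import (
    AnnotatedVariant,
    Category,
    ClinVarCall,
    Consequence,
    CVS_CODE,
    GenePanel,
    Genome,
    ParticipantPhenotype,
    Zygosity,
)

FIXTURE_NAMES = (
    "table2_occurrences",
    "mtdna_table",
    "literature_points",
    "paroxysmal_panel",
    "dntr_panel",
)

_NUMERIC = {
    "table2_occurrences": {"plp": int},
    "mtdna_table": {
        "heteroplasmy_pct": float,
        "n_domains": int,
        "clinvar_lp": int,
        "structure_exception": int,
    },
    "literature_points": {"families": int},
}


def _fixture_text(name: str) -> str:
    ref = resources.files("paroxscore").joinpath(f"data/{name}.tsv")
    return ref.read_text()


def _raw_frame(name: str) -> pd.DataFrame:
    """Fixture as an all-string frame; empty cells are empty strings."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    rows = list(csv.reader(_fixture_text(name).splitlines(), delimiter="\t"))
    header = rows[0]
    data = [r + [""] * (len(header) - len(r)) for r in rows[1:]]
    return pd.DataFrame(data, columns=header)


def regenerate_fixture_text(name: str) -> str:
    """Re-serialize a fixture from its parsed form in canonical layout.

    The packaged files are stored in exactly this layout (tab-separated,
    LF line endings, trailing empty cells stripped), so the regenerated
    text is byte-identical to the shipped copy — an integrity check that
    any edit to a fixture went through the canonical writer.
    """
    frame = _raw_frame(name)
    lines = ["\t".join(frame.columns)]
    for row in frame.itertuples(index=False):
        lines.append("\t".join(row).rstrip("\t"))
    return "\n".join(lines) + "\n"


def _panel(name: str, panel_name: str) -> GenePanel:
    frame = _raw_frame(name)
    return GenePanel(
        name=panel_name,
        genes=list(frame["gene"]),
        gene_phenotypes={
            g: {c for c in codes.split(",") if c}
            for g, codes in zip(frame["gene"], frame["phenotypes"])
        },
    )


def load_fixture(name: str):
    """Load a packaged fixture.

    Panels are returned as :class:`~paroxscore.models.GenePanel`; the other
    fixtures as typed :class:`pandas.DataFrame` objects.
    """
    if name == "paroxysmal_panel":
        return _panel(name, "paroxysmal")
    if name == "dntr_panel":
        return _panel(name, "dntr")
    frame = _raw_frame(name)
    for column, cast in _NUMERIC.get(name, {}).items():
        # keep object dtype so empty cells stay None, not NaN
        frame[column] = pd.Series(
            [None if s == "" else cast(s) for s in frame[column]],
            index=frame.index,
            dtype=object,
        )
    return frame


# -- Replaying the nuclear occurrence fixture through the full pipeline ------


def occurrence_fixture_as_cohort(
    af: float = 0.001, phylop: float = 2.5
) -> tuple[list[AnnotatedVariant], list[ParticipantPhenotype], GenePanel]:
    """Reconstruct a cohort whose annotations express the transcribed labels.

    Each occurrence row becomes an :class:`AnnotatedVariant` whose
    annotations satisfy the qualification predicates (rare and conserved by
    construction; clinvar/loss-of-function evidence for P/LP rows), and each
    Clinical row contributes its condition code to the carrier's phenotype
    record.  The returned panel extends the paroxysmal panel's phenotype
    sets with the fixture's condition codes, since the study's clinical
    correlations include gene-disease phenotypes beyond the paroxysmal
    abbreviations of the panel table.
    """
    occ = load_fixture("table2_occurrences")
    panel = load_fixture("paroxysmal_panel")

    diagnoses: dict[str, set[str]] = {}
    gene_phenos = {g: set(panel.gene_phenotypes.get(g, set())) for g in panel.genes}
    variants: list[AnnotatedVariant] = []
    for row in occ.itertuples(index=False):
        consequence = Consequence(row.consequence)
        lof = row.plp == 1 and consequence in (
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT,
        )
        calls = [ClinVarCall.P] if (row.plp == 1 and not lof) else []
        variants.append(
            AnnotatedVariant(
                participant_id=row.participant_id,
                gene=row.gene,
                genome=Genome.NUCLEAR,
                variant_id=row.variant_id,
                consequence=consequence,
                zygosity=Zygosity(row.zygosity),
                allele_freq={"nfe": af},
                phylop=phylop,
                clinvar_calls=calls,
                lof_predicted=lof,
                coseg_group=row.coseg_group or None,
                coding_equivalent=consequence is Consequence.REPEAT_EXPANSION,
            )
        )
        diagnoses.setdefault(row.participant_id, set())
        if row.cc_code:
            diagnoses[row.participant_id].add(row.cc_code)
            gene_phenos[row.gene].add(row.cc_code)

    phenotypes = [
        ParticipantPhenotype(participant_id=pid, paroxysmal_diagnoses=codes)
        for pid, codes in sorted(diagnoses.items())
    ]
    replay_panel = GenePanel(
        name="paroxysmal+study_correlates",
        genes=list(panel.genes),
        gene_phenotypes=gene_phenos,
    )
    # CVS itself must never act as a clinical correlate.
    for codes in replay_panel.gene_phenotypes.values():
        codes.discard(CVS_CODE)
    return variants, phenotypes, replay_panel


def mtdna_fixture_as_variants() -> list[AnnotatedVariant]:
    """The mitochondrial fixture as :class:`AnnotatedVariant` records."""
    frame = load_fixture("mtdna_table")
    return [
        AnnotatedVariant(
            participant_id=row.participant_id,
            gene=row.gene,
            genome=Genome.MITOCHONDRIAL,
            variant_id=row.variant_id,
            consequence=Consequence.MISSENSE,
            allele_freq={"nfe": 0.0},
            heteroplasmy_pct=row.heteroplasmy_pct,
            clinvar_calls=[ClinVarCall.LP] if row.clinvar_lp else [],
            structure_exception=bool(row.structure_exception),
        )
        for row in frame.itertuples(index=False)
    ]


def mtdna_fixture_domain_counts() -> dict[tuple[str, str], int]:
    """Published clinical-domain count per (participant, variant) record."""
    frame = load_fixture("mtdna_table")
    return {
        (row.participant_id, row.variant_id): row.n_domains
        for row in frame.itertuples(index=False)
    }


def transcribed_labels() -> dict[tuple[str, str, str], Category]:
    """Transcribed Key/Other label per (gene, participant, variant)."""
    occ = load_fixture("table2_occurrences")
    return {
        (row.gene, row.participant_id, row.variant_id): Category(row.category)
        for row in occ.itertuples(index=False)
    }
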