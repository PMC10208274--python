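import pytest

from paroxscore.models import (
    AnnotatedVariant,
    Consequence,
    GenePanel,
    Genome,
    ParticipantPhenotype,
    QualificationThresholds,
    Zygosity,
)


@pytest.fixture
def thresholds():
    return QualificationThresholds()


def make_variant(
    participant_id="P1",
    gene="SCN4A",
    genome=Genome.NUCLEAR,
    variant_id="p.Test1",
    consequence=Consequence.MISSENSE,
    af_nfe=0.001,
    phylop=2.5,
    **kwargs,
):
    """Variant factory with qualifying defaults."""
    allele_freq = {} if af_nfe is None else {"nfe": af_nfe}
    return AnnotatedVariant(
        participant_id=participant_id,
        gene=gene,
        genome=genome,
        variant_id=variant_id,
        consequence=consequence,
        allele_freq=allele_freq,
        phylop=phylop,
        **kwargs,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def small_panel():
    return GenePanel(
        name="test",
        genes=["SCN4A", "CACNA1A", "GLS2"],
        gene_phenotypes={"SCN4A": {"PP", "HOKPP"}, "CACNA1A": {"EAx", "FHM"}},
    )


@pytest.fixture
def phenotype_factory():
    def make(participant_id="P1", diagnoses=(), domains=()):
        return ParticipantPhenotype(
            participant_id=participant_id,
            paroxysmal_diagnoses=set(diagnoses),
            mito_domains=set(domains),
        )

    return make
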