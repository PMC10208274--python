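"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the composition observed in the study cohort: per
participant and panel gene, a qualifying occurrence arises at a configured
rate (default 0.04 per participant-gene, matching roughly 120 qualifying
occurrences across 80 participants and 35 genes); a configurable fraction
of qualifying occurrences is Key (default 0.26), of which a fraction is
P/LP-based (default 0.32) and the rest Clinical-based, expressed by giving
the carrier a matching non-CVS diagnosis.  Non-coding background variants
below the recording threshold are added at ``noncoding_rate``, and
mitochondrial records are drawn with configurable heteroplasmy and
clinical-domain distributions.

Determinism: the random stream is split per (participant, gene) from the
single seed, so adding a gene to a panel does not perturb any other gene's
draws, and a fixed seed yields byte-identical output tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_phenotype_table, write_variant_table
from .models import (
    AnnotatedVariant,
    ClinVarCall,
    Consequence,
    GenePanel,
    Genome,
    ParticipantPhenotype,
    ValidationError,
    Zygosity,
)

_MITO_GENES = ["ATP6", "COX1", "COX2", "COX3", "CYB", "ND1", "ND5", "TA", "TG", "TR"]
_DOMAIN_ORDER = [
    "neuromuscular",
    "neurodevelopmental",
    "neuropsychiatric",
    "functional",
    "endocrine",
    "immunological",
    "metabolic",
    "enzymological",
]


@dataclass
class MitoConfig:
    """Mitochondrial branch of the generator."""

    variants_per_participant: float = 0.2
    p_homoplasmic: float = 0.5
    heteroplasmy_range: tuple[float, float] = (5.0, 99.0)
    #: probability of each clinical-domain count 0..8
    domain_count_probs: tuple[float, ...] = (
        0.30, 0.20, 0.15, 0.10, 0.10, 0.06, 0.05, 0.03, 0.01,
    )
    clinvar_lp_rate: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.domain_count_probs) - 1.0) > 1e-9:
            raise ValidationError("domain_count_probs must sum to 1")


@dataclass
class SyntheticCohortConfig:
    """Generative parameters of a synthetic cohort."""

    n_participants: int = 80
    seed: int = 0
    panels: list[GenePanel] = field(default_factory=list)
    per_gene_qualifying_rate: dict[str, float] = field(default_factory=dict)
    default_qualifying_rate: float = 0.04
    key_fraction: float = 0.26
    plp_given_key: float = 0.32
    #: (mu, sigma) of ln(allele frequency) for rare qualifying variants
    af_lognormal_params: tuple[float, float] = (-8.0, 1.5)
    #: ((mean, sd) conserved, (mean, sd) non-conserved)
    phylop_mixture: tuple[tuple[float, float], tuple[float, float]] = (
        (3.0, 0.8),
        (0.3, 0.6),
    )
    noncoding_rate: float = 0.3
    mito: MitoConfig = field(default_factory=MitoConfig)
    phenotype_match_rate: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            "default_qualifying_rate": self.default_qualifying_rate,
            "key_fraction": self.key_fraction,
            "plp_given_key": self.plp_given_key,
            "noncoding_rate": self.noncoding_rate,
            "phenotype_match_rate": self.phenotype_match_rate,
            **{f"rate[{g}]": r for g, r in self.per_gene_qualifying_rate.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {p}")
        if self.n_participants < 0:
            raise ValidationError("n_participants must be non-negative")

    def rate(self, gene: str) -> float:
        return self.per_gene_qualifying_rate.get(gene, self.default_qualifying_rate)


def _gene_rng(seed: int, participant_index: int, gene: str) -> np.random.Generator:
    """Independent stream per (participant, gene), stable across panels."""
    return np.random.default_rng([seed, participant_index, zlib.crc32(gene.encode())])


def _draw_rare_af(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> float:
    mu, sigma = cfg.af_lognormal_params
    af = float(rng.lognormal(mu, sigma))
    return min(af, 0.0199)  # keep the draw strictly under the 2% cutoff


def _draw_plp_calls(rng: np.random.Generator) -> list[ClinVarCall]:
    """ClinVar multiset whose majority is P/LP (sizes 1-5)."""
    n = int(rng.integers(1, 6))
    n_plp = int(np.ceil(n / 2)) + int(rng.integers(0, n - int(np.ceil(n / 2)) + 1))
    calls = [ClinVarCall.P if rng.random() < 0.5 else ClinVarCall.LP for _ in range(n_plp)]
    calls += [ClinVarCall.VUS] * (n - n_plp)
    return calls


def _draw_minority_calls(rng: np.random.Generator) -> list[ClinVarCall]:
    """ClinVar multiset whose P/LP share stays strictly below half."""
    n = int(rng.integers(1, 6))
    max_plp = (n - 1) // 2
    n_plp = int(rng.integers(0, max_plp + 1))
    return [ClinVarCall.LP] * n_plp + [ClinVarCall.VUS] * (n - n_plp)


def _match_code(panel: GenePanel, gene: str) -> str | None:
    codes = sorted(panel.phenotypes(gene) - {"CVS"})
    return codes[0] if codes else None


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[AnnotatedVariant], list[ParticipantPhenotype]]:
    """Draw one cohort: the variant table and the phenotype table."""
    variants: list[AnnotatedVariant] = []
    phenotypes: list[ParticipantPhenotype] = []
    (mu_c, sd_c), (mu_n, sd_n) = config.phylop_mixture
    for i in range(config.n_participants):
        pid = f"S{i + 1:03d}"
        diagnoses: set[str] = set()
        for panel in config.panels:
            for gene in panel.genes:
                rng = _gene_rng(config.seed, i, gene)
                if rng.random() < config.phenotype_match_rate:
                    code = _match_code(panel, gene)
                    if code:
                        diagnoses.add(code)
                if rng.random() < config.rate(gene):
                    v_id = f"{gene}:q{i + 1}"
                    calls: list[ClinVarCall] = []
                    if rng.random() < config.key_fraction:
                        if rng.random() < config.plp_given_key:
                            calls = _draw_plp_calls(rng)
                        else:
                            code = _match_code(panel, gene)
                            if code is None:
                                calls = _draw_plp_calls(rng)
                            else:
                                diagnoses.add(code)
                    elif rng.random() < 0.3:
                        calls = _draw_minority_calls(rng)
                    variants.append(
                        AnnotatedVariant(
                            participant_id=pid,
                            gene=gene,
                            genome=Genome.NUCLEAR,
                            variant_id=v_id,
                            consequence=Consequence.MISSENSE,
                            zygosity=Zygosity.HET,
                            allele_freq={"nfe": _draw_rare_af(rng, config)},
                            phylop=max(float(rng.normal(mu_c, sd_c)), 1.5),
                            clinvar_calls=calls,
                        )
                    )
                if rng.random() < config.noncoding_rate:
                    variants.append(
                        AnnotatedVariant(
                            participant_id=pid,
                            gene=gene,
                            genome=Genome.NUCLEAR,
                            variant_id=f"{gene}:nc{i + 1}",
                            consequence=Consequence.INTRONIC,
                            zygosity=Zygosity.HET,
                            allele_freq={"nfe": float(rng.uniform(0.0, 0.0999))},
                            phylop=float(rng.normal(mu_n, sd_n)),
                        )
                    )
        mito_domains: set[str] = set()
        rng = _gene_rng(config.seed, i, "__mito__")
        n_mito = int(rng.poisson(config.mito.variants_per_participant))
        n_domains = int(rng.choice(9, p=config.mito.domain_count_probs))
        if n_mito > 0:
            mito_domains = set(_DOMAIN_ORDER[:n_domains])
        for k in range(n_mito):
            gene = str(rng.choice(_MITO_GENES))
            if rng.random() < config.mito.p_homoplasmic:
                het = None
            else:
                lo, hi = config.mito.heteroplasmy_range
                het = float(rng.uniform(lo, hi))
            lp = rng.random() < config.mito.clinvar_lp_rate
            variants.append(
                AnnotatedVariant(
                    participant_id=pid,
                    gene=gene,
                    genome=Genome.MITOCHONDRIAL,
                    variant_id=f"{gene}:m{i + 1}.{k}",
                    consequence=Consequence.MISSENSE,
                    allele_freq={"nfe": 0.0},
                    heteroplasmy_pct=het,
                    clinvar_calls=[ClinVarCall.LP] if lp else [],
                )
            )
        phenotypes.append(
            ParticipantPhenotype(
                participant_id=pid,
                paroxysmal_diagnoses=diagnoses,
                mito_domains=mito_domains,
                ancestry_label="nfe",
            )
        )
    return variants, phenotypes


def synthetic_panel(n_genes: int, name: str = "synthetic") -> GenePanel:
    """A panel of ``n_genes`` synthetic genes, each with its own distinct
    phenotype code so Clinical matches never leak across genes."""
    genes = [f"G{k + 1:03d}" for k in range(n_genes)]
    return GenePanel(
        name=name,
        genes=genes,
        gene_phenotypes={g: {f"MATCH_{g}"} for g in genes},
    )


def generate_null_pair(
    config: SyntheticCohortConfig, n_genes_a: int, n_genes_b: int
) -> tuple[list[AnnotatedVariant], list[ParticipantPhenotype], GenePanel, GenePanel]:
    """Two panels with identical per-gene generative rates: any burden
    difference between them is sampling noise."""
    panel_a = GenePanel(name="null_a", genes=[f"NULLA{k + 1}" for k in range(n_genes_a)])
    panel_b = GenePanel(name="null_b", genes=[f"NULLB{k + 1}" for k in range(n_genes_b)])
    cfg = SyntheticCohortConfig(
        n_participants=config.n_participants,
        seed=config.seed,
        panels=[panel_a, panel_b],
        default_qualifying_rate=config.default_qualifying_rate,
        key_fraction=config.key_fraction,
        plp_given_key=config.plp_given_key,
        af_lognormal_params=config.af_lognormal_params,
        phylop_mixture=config.phylop_mixture,
        noncoding_rate=0.0,
        mito=MitoConfig(variants_per_participant=0.0),
    )
    variants, phenotypes = generate_cohort(cfg)
    return variants, phenotypes, panel_a, panel_b


def simulate_to_dir(config: SyntheticCohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write the two TSVs in the canonical dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants, phenotypes = generate_cohort(config)
    variant_path = out_dir / "variants.tsv"
    phenotype_path = out_dir / "phenotypes.tsv"
    write_variant_table(variants, variant_path)
    write_phenotype_table(phenotypes, phenotype_path)
    return {"variants": variant_path, "phenotypes": phenotype_path}
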