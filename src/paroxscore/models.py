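"""Domain types for the candidate-gene discovery pipeline.

The analysis treats one participant x variant record as the atomic unit
(:class:`AnnotatedVariant`), carries per-participant clinical context in
:class:`ParticipantPhenotype`, and derives qualification categories and
per-gene scores from them.  All types are plain dataclasses with eager
validation so that malformed rows fail loudly at construction time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Genome(str, enum.Enum):
    NUCLEAR = "nuclear"
    MITOCHONDRIAL = "mitochondrial"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE_PREDICTED = "splice_site_predicted"
    SYNONYMOUS = "synonymous"
    UTR = "utr"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    REPEAT_EXPANSION = "repeat_expansion"
    STRUCTURAL_DELETION = "structural_deletion"
    STRUCTURAL_DUPLICATION = "structural_duplication"


#: Consequences that alter the amino-acid sequence outright (splice evidence
#: is handled separately through the splice scores).
CODING_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
    }
)

#: Consequences with a high prediction of loss of function on protein level.
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.STRUCTURAL_DELETION,
    }
)

#: Record types whose qualification cannot be derived from allele frequency
#: and conservation (no frequency rule exists for repeat alleles); they carry
#: an explicit coding-equivalent flag instead.
FLAG_QUALIFIED_CONSEQUENCES = frozenset(
    {
        Consequence.REPEAT_EXPANSION,
        Consequence.STRUCTURAL_DELETION,
        Consequence.STRUCTURAL_DUPLICATION,
    }
)


class ClinVarCall(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Category(str, enum.Enum):
    KEY = "key"
    OTHER = "other"
    RECORDED_ONLY = "recorded_only"
    NOT_RECORDED = "not_recorded"


class MitoCategory(str, enum.Enum):
    KEY = "key"
    OTHER = "other"
    EXCLUDED = "excluded"


class Tier(enum.IntEnum):
    """Evidence tiers, ordered so that ``max`` picks the stronger tier."""

    NO_EVIDENCE = 0
    POSSIBLY = 1
    LIKELY = 2
    HIGHLY_LIKELY = 3

    @property
    def label(self) -> str:
        return self.name.lower()


#: The eight mitochondrial clinical domains counted toward the Clinical rule.
MITO_DOMAINS = frozenset(
    {
        "neuromuscular",
        "neurodevelopmental",
        "neuropsychiatric",
        "functional",
        "endocrine",
        "immunological",
        "metabolic",
        "enzymological",
    }
)

#: Reserved gene symbol under which all mitochondrial variants are pooled.
MTDNA_GENE = "mtDNA"

#: Phenotype code for cyclic vomiting syndrome itself; never counts as a
#: clinical match (that would be circular).
CVS_CODE = "CVS"


class ValidationError(ValueError):
    """A record field violates its documented range or consistency rule."""


class FormatError(ValueError):
    """An input table is structurally malformed (e.g. missing column)."""


def _check_unit(value: float | None, name: str) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_pct(value: float | None, name: str) -> None:
    if value is not None and not (0.0 <= value <= 100.0):
        raise ValidationError(f"{name} must lie in [0, 100], got {value!r}")


@dataclass
class AnnotatedVariant:
    """One participant x variant record with its laboratory annotations."""

    participant_id: str
    gene: str
    genome: Genome
    variant_id: str
    consequence: Consequence
    zygosity: Zygosity = Zygosity.HET
    allele_freq: dict[str, float] = field(default_factory=dict)
    phylop: float | None = None
    mammal_match_pct: float | None = None
    splice_rf: float | None = None
    splice_ada: float | None = None
    clinvar_calls: list[ClinVarCall] = field(default_factory=list)
    lof_predicted: bool = False
    heteroplasmy_pct: float | None = None
    structure_exception: bool = False
    coseg_group: str | None = None
    coding_equivalent: bool = False

    def __post_init__(self) -> None:
        self.genome = Genome(self.genome)
        self.consequence = Consequence(self.consequence)
        self.zygosity = Zygosity(self.zygosity)
        self.clinvar_calls = [ClinVarCall(c) for c in self.clinvar_calls]
        for pop, af in self.allele_freq.items():
            _check_unit(af, f"allele_freq[{pop}]")
        _check_unit(self.splice_rf, "splice_rf")
        _check_unit(self.splice_ada, "splice_ada")
        _check_pct(self.mammal_match_pct, "mammal_match_pct")
        _check_pct(self.heteroplasmy_pct, "heteroplasmy_pct")
        if self.genome is Genome.NUCLEAR:
            if self.heteroplasmy_pct is not None:
                raise ValidationError(
                    "heteroplasmy_pct is only meaningful for mitochondrial records"
                )
            if self.structure_exception:
                raise ValidationError(
                    "structure_exception is only meaningful for mitochondrial records"
                )

    def frequency(self, population: str) -> float:
        """Allele frequency in *population*; absence from gnomAD is taken as 0
        (absence is the strongest rarity evidence)."""
        return self.allele_freq.get(population, 0.0)


@dataclass
class ParticipantPhenotype:
    """Per-participant non-CVS paroxysmal diagnoses and mito domain findings."""

    participant_id: str
    paroxysmal_diagnoses: set[str] = field(default_factory=set)
    mito_domains: set[str] = field(default_factory=set)
    ancestry_label: str = ""

    def __post_init__(self) -> None:
        self.paroxysmal_diagnoses = set(self.paroxysmal_diagnoses)
        self.mito_domains = set(self.mito_domains)
        unknown = self.mito_domains - MITO_DOMAINS
        if unknown:
            raise ValidationError(
                f"unknown mito domain label(s) {sorted(unknown)}; "
                f"allowed: {sorted(MITO_DOMAINS)}"
            )


@dataclass
class GenePanel:
    """A named gene list with per-gene associated paroxysmal phenotypes."""

    name: str
    genes: list[str]
    gene_phenotypes: dict[str, set[str]] = field(default_factory=dict)
    mito_as_single_gene: bool = True

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"panel {self.name!r} has duplicate genes")
        self.gene_phenotypes = {
            g: set(p) for g, p in self.gene_phenotypes.items()
        }
        for g in self.gene_phenotypes:
            if g not in self.genes:
                raise ValidationError(
                    f"phenotypes given for gene {g!r} absent from panel {self.name!r}"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def phenotypes(self, gene: str) -> set[str]:
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} not in panel {self.name!r}")
        return self.gene_phenotypes.get(gene, set())


@dataclass
class QualificationThresholds:
    """Cutoffs of the variant rules.

    Frequency comparisons are strict (<), conservation inclusive (>=) and
    splice strict (>), mirroring how the rules are stated.
    """

    af_record_max: float = 0.10
    af_qualify_max: float = 0.02
    phylop_min: float = 1.5
    mammal_match_min_pct: float = 90.0
    splice_min: float = 0.6
    comparison_population: str = "nfe"

    def __post_init__(self) -> None:
        _check_unit(self.af_record_max, "af_record_max")
        _check_unit(self.af_qualify_max, "af_qualify_max")
        _check_unit(self.splice_min, "splice_min")
        _check_pct(self.mammal_match_min_pct, "mammal_match_min_pct")
        if self.af_qualify_max > self.af_record_max:
            raise ValidationError(
                "af_qualify_max must not exceed af_record_max "
                f"({self.af_qualify_max} > {self.af_record_max})"
            )


@dataclass
class QualificationResult:
    """Derived category for one occurrence group (one or more co-segregating
    records of a single participant in a single gene)."""

    participant_id: str
    gene: str
    variants: list[AnnotatedVariant]
    recorded: bool
    qualifying: bool
    plp: bool
    clinical: bool
    category: Category

    def __post_init__(self) -> None:
        # Nesting and category/flag consistency are structural invariants.
        if self.category is Category.KEY and not (
            self.qualifying and (self.plp or self.clinical)
        ):
            raise ValidationError("key category requires qualifying and (plp or clinical)")
        if self.category is Category.OTHER and not (
            self.qualifying and not self.plp and not self.clinical
        ):
            raise ValidationError("other category requires qualifying without plp/clinical")
        if self.qualifying and not self.recorded:
            raise ValidationError("qualifying implies recorded")

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


@dataclass
class MitoClassification:
    """Classification of one mitochondrial record."""

    variant: AnnotatedVariant
    excluded_somatic: bool
    plp: bool
    clinical: bool
    category: MitoCategory

    def __post_init__(self) -> None:
        if self.excluded_somatic and self.category is not MitoCategory.EXCLUDED:
            raise ValidationError("excluded_somatic records must be categorized excluded")


@dataclass
class GeneScore:
    """Per-gene occurrence counts, points, and evidence tiers."""

    gene: str
    key_occurrences: int
    other_occurrences: int
    literature_families: int = 0

    def __post_init__(self) -> None:
        for name in ("key_occurrences", "other_occurrences", "literature_families"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def study_points(self) -> int:
        return 3 * self.key_occurrences + self.other_occurrences

    @property
    def literature_points(self) -> int:
        return self.literature_families

    @property
    def study_tier(self) -> Tier:
        from .scoring import assign_tier

        return assign_tier(self.study_points)

    @property
    def literature_tier(self) -> Tier:
        from .scoring import assign_tier

        return assign_tier(self.literature_points)

    @property
    def composite_tier(self) -> Tier:
        return max(self.study_tier, self.literature_tier)


@dataclass
class Contingency2x2:
    """A 2x2 contingency table: rows are groups, columns outcome/non-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValidationError(f"contingency cells must be non-negative: {cells}")
        if sum(cells) == 0:
            raise ValidationError("contingency table must have at least one positive margin")

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class FisherResult:
    """Two-tailed Fisher exact test outcome."""

    p_two_tailed: float
    odds_ratio: float
    table: Contingency2x2
    correction: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_tailed <= 1.0 + 1e-15):
            raise ValidationError(f"p-value out of (0, 1]: {self.p_two_tailed}")
        if not (self.odds_ratio >= 0 or math.isnan(self.odds_ratio)):
            raise ValidationError(f"odds ratio must be non-negative: {self.odds_ratio}")
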