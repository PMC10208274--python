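"""Reading and writing of annotated variant and phenotype tables.

The canonical interchange format is a TSV with one row per participant x
variant (the shape of the laboratory annotation exports the analysis was
designed around).  VCF ingestion is supported as a convenience: multi-sample
records are exploded to per-participant rows with genotype-derived zygosity,
and annotations are picked up from INFO keys.

Empty cells mean "absent"; absent optional fields stay absent (``None``)
rather than being zero-filled.  Variant coordinates are never interpreted:
``variant_id`` is an opaque key.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .models import (
    AnnotatedVariant,
    ClinVarCall,
    Consequence,
    FormatError,
    Genome,
    ParticipantPhenotype,
    ValidationError,
    Zygosity,
)

#: Exact header of the variant TSV dialect.
VARIANT_COLUMNS = [
    "participant_id",
    "gene",
    "genome",
    "variant_id",
    "consequence",
    "zygosity",
    "af_nfe",
    "af_afr",
    "af_global",
    "phylop",
    "mammal_match_pct",
    "splice_rf",
    "splice_ada",
    "clinvar_calls",
    "lof_predicted",
    "heteroplasmy_pct",
    "structure_exception",
    "coseg_group",
    "coding_equivalent",
]

PHENOTYPE_COLUMNS = [
    "participant_id",
    "paroxysmal_diagnoses",
    "mito_domains",
    "ancestry_label",
]

#: Population label per TSV frequency column.
_AF_COLUMNS = {"af_nfe": "nfe", "af_afr": "afr", "af_global": "global"}

#: INFO keys consumed when reading VCF.
_VCF_AF_KEYS = {
    "GNOMAD_AF_NFE": "nfe",
    "GNOMAD_AF_AFR": "afr",
    "GNOMAD_AF": "global",
}


def _opt_float(cell: str, column: str, row_no: int) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(
            f"row {row_no}: column {column!r} is not numeric: {cell!r}"
        ) from exc


def _opt_bool(cell: str) -> bool:
    return cell not in ("", "0")


def _row_to_variant(row: dict[str, str], row_no: int) -> AnnotatedVariant:
    allele_freq = {}
    for column, pop in _AF_COLUMNS.items():
        value = _opt_float(row[column], column, row_no)
        if value is not None:
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"row {row_no}: allele frequency {column}={value} outside [0, 1]"
                )
            allele_freq[pop] = value
    calls = [c for c in row["clinvar_calls"].split(",") if c]
    try:
        return AnnotatedVariant(
            participant_id=row["participant_id"],
            gene=row["gene"],
            genome=Genome(row["genome"]),
            variant_id=row["variant_id"],
            consequence=Consequence(row["consequence"]),
            zygosity=Zygosity(row["zygosity"]) if row["zygosity"] else Zygosity.HET,
            allele_freq=allele_freq,
            phylop=_opt_float(row["phylop"], "phylop", row_no),
            mammal_match_pct=_opt_float(row["mammal_match_pct"], "mammal_match_pct", row_no),
            splice_rf=_opt_float(row["splice_rf"], "splice_rf", row_no),
            splice_ada=_opt_float(row["splice_ada"], "splice_ada", row_no),
            clinvar_calls=[ClinVarCall(c) for c in calls],
            lof_predicted=_opt_bool(row["lof_predicted"]),
            heteroplasmy_pct=_opt_float(row["heteroplasmy_pct"], "heteroplasmy_pct", row_no),
            structure_exception=_opt_bool(row["structure_exception"]),
            coseg_group=row["coseg_group"] or None,
            coding_equivalent=_opt_bool(row["coding_equivalent"]),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {row_no}: {exc}") from exc
    except ValueError as exc:
        raise ValidationError(f"row {row_no}: {exc}") from exc


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[AnnotatedVariant]:
    """Read an annotated variant table.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"tsv"`` for the canonical tab-separated dialect, ``"vcf"`` for a
        (multi-sample) VCF carrying the documented INFO keys.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _read_variant_tsv(path: str | Path) -> list[AnnotatedVariant]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t", restval="")
        header = reader.fieldnames or []
        missing = [c for c in VARIANT_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: variant table is missing mandatory column(s): {', '.join(missing)}"
            )
        return [
            _row_to_variant({k: (v or "") for k, v in row.items()}, row_no)
            for row_no, row in enumerate(reader, start=2)
        ]


def write_variant_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Write variants in the canonical TSV dialect (round-trips exactly)."""

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in variants:
            writer.writerow(
                [
                    v.participant_id,
                    v.gene,
                    v.genome.value,
                    v.variant_id,
                    v.consequence.value,
                    v.zygosity.value,
                    fmt(v.allele_freq.get("nfe")),
                    fmt(v.allele_freq.get("afr")),
                    fmt(v.allele_freq.get("global")),
                    fmt(v.phylop),
                    fmt(v.mammal_match_pct),
                    fmt(v.splice_rf),
                    fmt(v.splice_ada),
                    ",".join(c.value for c in v.clinvar_calls),
                    fmt(v.lof_predicted),
                    fmt(v.heteroplasmy_pct),
                    fmt(v.structure_exception),
                    v.coseg_group or "",
                    fmt(v.coding_equivalent),
                ]
            )


def read_phenotype_table(path: str | Path) -> list[ParticipantPhenotype]:
    """Read the participant phenotype TSV."""
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t", restval="")
        header = reader.fieldnames or []
        missing = [c for c in PHENOTYPE_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: phenotype table is missing mandatory column(s): {', '.join(missing)}"
            )
        out = []
        for row_no, row in enumerate(reader, start=2):
            row = {k: (v or "") for k, v in row.items()}
            try:
                out.append(
                    ParticipantPhenotype(
                        participant_id=row["participant_id"],
                        paroxysmal_diagnoses={
                            c for c in row["paroxysmal_diagnoses"].split(",") if c
                        },
                        mito_domains={c for c in row["mito_domains"].split(",") if c},
                        ancestry_label=row["ancestry_label"],
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from exc
        return out


def write_phenotype_table(
    phenotypes: Iterable[ParticipantPhenotype], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PHENOTYPE_COLUMNS)
        for p in phenotypes:
            writer.writerow(
                [
                    p.participant_id,
                    ",".join(sorted(p.paroxysmal_diagnoses)),
                    ",".join(sorted(p.mito_domains)),
                    p.ancestry_label,
                ]
            )


# -- VCF ingestion -----------------------------------------------------------

_CSQ_MAP = {
    "missense_variant": Consequence.MISSENSE,
    "missense": Consequence.MISSENSE,
    "stop_gained": Consequence.NONSENSE,
    "nonsense": Consequence.NONSENSE,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frameshift": Consequence.FRAMESHIFT,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "splice_site_predicted": Consequence.SPLICE_SITE_PREDICTED,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "synonymous": Consequence.SYNONYMOUS,
    "5_prime_UTR_variant": Consequence.UTR,
    "3_prime_UTR_variant": Consequence.UTR,
    "utr": Consequence.UTR,
    "intron_variant": Consequence.INTRONIC,
    "intronic": Consequence.INTRONIC,
    "intergenic_variant": Consequence.INTERGENIC,
    "intergenic": Consequence.INTERGENIC,
}

_PLP_TOKENS = {"pathogenic", "likely_pathogenic"}


def _clnsig_to_calls(raw: str) -> list[ClinVarCall]:
    calls = []
    for token in raw.replace("|", "/").split("/"):
        token = token.strip().lower()
        if token == "pathogenic":
            calls.append(ClinVarCall.P)
        elif token == "likely_pathogenic":
            calls.append(ClinVarCall.LP)
        elif token == "uncertain_significance":
            calls.append(ClinVarCall.VUS)
        elif token == "likely_benign":
            calls.append(ClinVarCall.LB)
        elif token == "benign":
            calls.append(ClinVarCall.B)
    return calls


def _read_variant_vcf(path: str | Path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[AnnotatedVariant] = []
    for record in vcf:
        info = dict(record.INFO)
        gene = info.get("GENE", "")
        mito = record.CHROM.lstrip("chr") in ("M", "MT")
        csq = str(info.get("CSQ", "missense")).split("&")[0].split(",")[0]
        consequence = _CSQ_MAP.get(csq, Consequence.MISSENSE)
        allele_freq = {
            pop: float(info[key]) for key, pop in _VCF_AF_KEYS.items() if key in info
        }
        calls = _clnsig_to_calls(str(info.get("CLNSIG", "")))
        variant_id = f"{record.CHROM}:{record.POS}:{record.REF}>{','.join(record.ALT)}"
        for sample, gt in zip(samples, record.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt == 0:
                continue
            if len(alleles) == 1:
                zygosity = Zygosity.HEMI
            elif n_alt == len(alleles):
                zygosity = Zygosity.HOM
            else:
                zygosity = Zygosity.HET
            out.append(
                AnnotatedVariant(
                    participant_id=sample,
                    gene=str(gene),
                    genome=Genome.MITOCHONDRIAL if mito else Genome.NUCLEAR,
                    variant_id=variant_id,
                    consequence=consequence,
                    zygosity=zygosity,
                    allele_freq=allele_freq,
                    phylop=float(info["PHYLOP"]) if "PHYLOP" in info else None,
                    splice_rf=float(info["SPLICE_RF"]) if "SPLICE_RF" in info else None,
                    splice_ada=float(info["SPLICE_ADA"]) if "SPLICE_ADA" in info else None,
                    clinvar_calls=calls,
                    lof_predicted=consequence
                    in (Consequence.NONSENSE, Consequence.FRAMESHIFT),
                )
            )
    return out
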