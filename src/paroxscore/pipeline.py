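"""End-to-end pipeline: qualification -> mtDNA classification -> scoring ->
cohort statistics, with per-stage tables and a summary report.

Every number in the summary is recomputable from the stage tables it cites;
percentages are reported to the nearest integer, rounding half away from
zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .fixtures import load_fixture
from .models import (
    Category,
    GenePanel,
    Genome,
    MTDNA_GENE,
    QualificationThresholds,
    Tier,
)
from .io import read_phenotype_table, read_variant_table
from .mtdna import classify_mito
from .qualification import detect_recessive_candidates, qualify_cohort
from .scoring import (
    build_candidate_list,
    score_mtdna,
    score_panel,
    scores_to_frame,
)
from .stats import categorize_recorded

logger = logging.getLogger("paroxscore")


def round_half_away_pct(numerator: int, denominator: int) -> int:
    """Integer percentage, half away from zero."""
    if denominator == 0:
        return 0
    x = 100.0 * numerator / denominator
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    variant_path: str | Path
    phenotype_path: str | Path
    out_dir: str | Path
    panel: str | GenePanel = "paroxysmal_panel"
    thresholds: QualificationThresholds = field(default_factory=QualificationThresholds)
    report_format: str = "tsv"
    variant_dialect: str = "tsv"
    literature: bool = True

    def resolve_panel(self) -> GenePanel:
        if isinstance(self.panel, GenePanel):
            return self.panel
        return load_fixture(self.panel)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report bundle; returns the summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = config.resolve_panel()

    stage = "read_inputs"
    try:
        variants = read_variant_table(config.variant_path, dialect=config.variant_dialect)
        phenotypes = read_phenotype_table(config.phenotype_path)

        stage = "qualification"
        nuclear = [v for v in variants if v.genome is Genome.NUCLEAR]
        panel_records = [v for v in nuclear if v.gene in panel]
        results = qualify_cohort(panel_records, phenotypes, panel, config.thresholds)
        _write_results_table(results, out_dir / "qualification.tsv")

        stage = "mtdna"
        mito = [v for v in variants if v.genome is Genome.MITOCHONDRIAL]
        mito_classes = classify_mito(mito, phenotypes)
        _write_mito_table(mito_classes, out_dir / "mtdna_classification.tsv")

        stage = "scoring"
        literature = {}
        if config.literature:
            lit = load_fixture("literature_points")
            literature = dict(zip(lit["gene"], lit["families"]))
        scores = score_panel(results, panel, literature)
        if mito_classes:
            scores[MTDNA_GENE] = score_mtdna(mito_classes)
        frame = scores_to_frame(scores).sort_values(
            ["study_points", "gene"], ascending=[False, True], kind="mergesort"
        )
        frame.to_csv(out_dir / "gene_scores.tsv", sep="\t", index=False)
        if config.report_format == "json":
            frame.to_json(out_dir / "gene_scores.json", orient="records", indent=2)

        stage = "statistics"
        recorded_classes = categorize_recorded(results, config.thresholds)
        recessive = detect_recessive_candidates(results)

        stage = "summary"
        candidates = build_candidate_list(scores)
        n = len(phenotypes)
        key_carriers = {r.participant_id for r in results if r.category is Category.KEY}
        qual_carriers = {r.participant_id for r in results if r.qualifying}
        summary = {
            "n_participants": n,
            "panel": panel.name,
            "n_panel_genes": len(panel.genes),
            "candidate_genes": [
                {
                    "gene": s.gene,
                    "study_points": s.study_points,
                    "composite_tier": s.composite_tier.label,
                }
                for s in candidates
            ],
            "n_candidate_genes": len(candidates),
            "tier_counts": {
                tier.label: sum(
                    1 for s in scores.values() if s.gene != MTDNA_GENE and s.study_tier is tier
                )
                for tier in Tier
            },
            "participants_with_key": {
                "count": len(key_carriers),
                "denominator": n,
                "pct": round_half_away_pct(len(key_carriers), n),
            },
            "participants_with_qualifying": {
                "count": len(qual_carriers),
                "denominator": n,
                "pct": round_half_away_pct(len(qual_carriers), n),
            },
            "recorded_variant_classes": recorded_classes,
            "recessive_candidates": [
                {"participant_id": p, "gene": g, "occurrences": k} for p, g, k in recessive
            ],
        }
        with open(out_dir / "summary.json", "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")
        return summary
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        raise


def _write_results_table(results, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "participant_id", "variant_ids", "recorded", "qualifying", "plp", "clinical", "category"]
        )
        for r in results:
            writer.writerow(
                [
                    r.gene,
                    r.participant_id,
                    ",".join(r.variant_ids),
                    int(r.recorded),
                    int(r.qualifying),
                    int(r.plp),
                    int(r.clinical),
                    r.category.value,
                ]
            )


def _write_mito_table(classes, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "participant_id", "variant_id", "excluded_somatic", "plp", "clinical", "category"]
        )
        for c in classes:
            writer.writerow(
                [
                    c.variant.gene,
                    c.variant.participant_id,
                    c.variant.variant_id,
                    int(c.excluded_somatic),
                    int(c.plp),
                    int(c.clinical),
                    c.category.value,
                ]
            )
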