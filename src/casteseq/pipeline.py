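"""End-to-end orchestration and summary reporting.

``run_pipeline`` executes normalize -> DE call -> annotate -> orthology
projection -> novelty enrichment on a count matrix (real or simulated) and
returns a report bundle: per-stage call tables, a headline summary of
DEG/HDEG counts and top OFC per phenotype, annotation-class counts for the
HDEGs, and the configuration (seeds included) that produced them.  The run
is deterministic under a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .containers import CountMatrix, STAGES, phenotype_label
from . import annotation as ann
from . import counts as cn
from . import diffexpr as de
from . import orthology as orth


@dataclass
class RunConfig:
    """Declarative options for a pipeline run."""

    excluded_samples: list[str] = field(default_factory=list)
    target_depth: int | str = "min"
    n_draws: int = 10
    seed: int = 0
    min_corr: float = 0.9
    evalue_threshold: float = ann.EVALUE_THRESHOLD
    novelty_columns: str = "total"

    def as_dict(self) -> dict[str, Any]:
        return {
            "excluded_samples": list(self.excluded_samples),
            "target_depth": self.target_depth,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "min_corr": self.min_corr,
            "evalue_threshold": self.evalue_threshold,
            "novelty_columns": self.novelty_columns,
        }


@dataclass
class ReportBundle:
    config: dict[str, Any]
    qc: pd.DataFrame
    calls_by_stage: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    class_counts: pd.DataFrame | None
    novelty: list | None
    deo_counts: dict[str, int] | None


def _stage_of(label: str) -> str:
    return {"E": "early", "M": "mid", "L": "late"}[label[0]]


def summarize_calls(calls_by_stage: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Headline table: DEG count, HDEG count and top OFC per phenotype."""
    rows = {}
    for stage, calls in calls_by_stage.items():
        for caste in ("Q", "W"):
            label = phenotype_label(stage, caste)
            sub = calls[(calls["direction"] == caste) & calls["is_deg"]]
            hdegs = calls[(calls["direction"] == caste)
                          & calls["is_hdeg"].fillna(False).astype(bool)]
            top = float(sub["ofc"].max()) if len(sub) else float("nan")
            rows[label] = {
                "degs": int(len(sub)),
                "hdegs": int(len(hdegs)),
                "top_ofc": round(top, 3) if pd.notna(top) else top,
            }
    order = [p for p in ("EQ", "EW", "MQ", "MW", "LQ", "LW") if p in rows]
    out = pd.DataFrame({k: rows[k] for k in order}).T
    return out.astype({"degs": int, "hdegs": int})


def run_pipeline(
    matrix: CountMatrix,
    config: RunConfig | None = None,
    hit_table: pd.DataFrame | None = None,
    annotated_ids: set[str] | None = None,
    coding_flags: dict[str, bool] | None = None,
    ortho_ab: pd.DataFrame | None = None,
    ortho_ba: pd.DataFrame | None = None,
) -> ReportBundle:
    """Run the core analysis on a raw count matrix.

    Stages: explicit sample exclusion, subsampling normalization, replicate
    QC, per-stage DEG/HDEG calling, optional annotation classification and
    novelty enrichment (when a hit table is given), optional orthologue
    projection (when cross-species hit tables are given).  Failures carry
    the stage name.
    """
    config = config or RunConfig()
    stage_name = "exclude"
    try:
        if config.excluded_samples:
            matrix = matrix.drop_samples(config.excluded_samples)
        stage_name = "normalize"
        norm = cn.subsample_normalize(
            matrix, target_depth=config.target_depth,
            n_draws=config.n_draws, seed=config.seed,
        )
        stage_name = "qc"
        qc = cn.replicate_qc(norm, min_corr=config.min_corr)
        stage_name = "de-call"
        intervals = de.group_intervals(norm)
        stages_present = [s for s in STAGES
                          if s in set(norm.metadata.loc[list(norm.counts.columns), "stage"])]
        calls_by_stage = {}
        for stage in stages_present:
            calls = de.call_degs(intervals, stage)
            calls_by_stage[stage] = de.call_hdegs(calls)
        summary = summarize_calls(calls_by_stage)

        class_counts = None
        novelty = None
        if hit_table is not None:
            stage_name = "annotate"
            annotations = ann.classify_table(
                hit_table,
                annotated_ids=annotated_ids or set(),
                coding_flags=coding_flags or {},
                feature_ids=list(matrix.feature_ids),
                evalue_threshold=config.evalue_threshold,
            )
            hdegs_by_pheno = {}
            for stage, calls in calls_by_stage.items():
                for caste in ("Q", "W"):
                    hdegs_by_pheno[phenotype_label(stage, caste)] = de.hdeg_features(
                        calls, direction=caste
                    )
            counts_rows = []
            for label, feats in hdegs_by_pheno.items():
                cls_counts = annotations.loc[sorted(feats), "annotation_class"].value_counts()
                counts_rows.append({"phenotype": label, **cls_counts.to_dict()})
            class_counts = (
                pd.DataFrame(counts_rows).set_index("phenotype").fillna(0).astype(int)
            )
            novelty = ann.novelty_enrichment(
                hdegs_by_pheno, annotations, columns=config.novelty_columns
            )

        deo_counts = None
        if ortho_ab is not None and ortho_ba is not None:
            stage_name = "orthology"
            omap = orth.rbh(ortho_ab, ortho_ba)
            deg_lists = {}
            for stage, calls in calls_by_stage.items():
                for caste in ("Q", "W"):
                    deg_lists[phenotype_label(stage, caste)] = de.deg_features(
                        calls, direction=caste
                    )
            deos = orth.project_lists(deg_lists, omap)
            deo_counts = {k: len(v) for k, v in deos.items()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    return ReportBundle(
        config=config.as_dict(),
        qc=qc,
        calls_by_stage=calls_by_stage,
        summary=summary,
        class_counts=class_counts,
        novelty=novelty,
        deo_counts=deo_counts,
    )


def render_report(bundle: ReportBundle) -> str:
    """Plain-text report of a run (byte-stable under a fixed configuration)."""
    lines = ["# casteseq run report", "#", "# configuration:"]
    for k, v in sorted(bundle.config.items()):
        lines.append(f"#   {k} = {v}")
    lines.append("")
    lines.append("## per-phenotype summary (DEGs, HDEGs, top OFC)")
    lines.append(bundle.summary.to_csv(sep="\t"))
    if bundle.class_counts is not None:
        lines.append("## HDEG annotation-class counts")
        lines.append(bundle.class_counts.to_csv(sep="\t"))
    if bundle.novelty is not None:
        lines.append("## novelty enrichment (W-up vs Q-up HDEGs)")
        for res in bundle.novelty:
            p = "untestable" if not res.testable else f"{res.p:.3f}"
            lines.append(f"{res.stage}\t{res.table}\t{p}")
        lines.append("")
    if bundle.deo_counts is not None:
        lines.append("## DEO counts (DEGs with an orthologue)")
        for k, v in sorted(bundle.deo_counts.items()):
            lines.append(f"{k}\t{v}")
        lines.append("")
    lines.append("## replicate QC")
    lines.append(bundle.qc.to_csv(sep="\t"))
    return "\n".join(lines)
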