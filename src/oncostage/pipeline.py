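"""End-to-end orchestration of the stagewise biomarker discovery pipeline.

From an annotated log2 expression matrix: filter, antilog to pseudo-counts,
compute precision weights, fit the baseline and cell-means moderated linear
models, run the stage-vs-control and between-stage contrasts, apply the
salience criteria, fit the numeric-stage monotone model, intersect to the
progression-significant set, and assemble the diagnostic feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import salience as sal
from .datatypes import AnnotatedExpression, to_pseudocounts
from .io import FilterReport, apply_filters
from .linmod import (
    ContrastResults,
    ModeratedFitResults,
    StageLinearModel,
    summarize_linear_top,
)
from .monotone import (
    MonotoneTrendModel,
    intersect_progression,
    linear_monotone_overlap,
    meg_counts,
)
from .screening import FeaturePanel, assemble_feature_space
from .voom import VoomResult, voom_transform
from .linmod import build_design


@dataclass
class PipelineResults:
    """Bundle of every intermediate and final table of one pipeline run."""

    dataset: AnnotatedExpression
    filter_report: FilterReport
    voom: VoomResult
    baseline: ModeratedFitResults
    cellmeans: ModeratedFitResults
    contrast_sc: ContrastResults
    contrast_between: ContrastResults
    linear_table: pd.DataFrame
    salience_records: pd.DataFrame
    salient_counts: pd.Series
    stage_tables: dict[str, pd.DataFrame]
    monotone_records: pd.DataFrame
    meg_counts: pd.Series
    progression: pd.DataFrame
    feature_panel: FeaturePanel

    def summary(self) -> str:
        lines = [
            "Stagewise biomarker discovery run",
            "=" * 40,
            str(self.filter_report),
            f"significant linear-model genes: {int(self.linear_table['significant'].sum())}",
            "stage-salient genes: "
            + ", ".join(f"{s}: {self.salient_counts[s]}" for s in ("I", "II", "III", "IV")),
            f"genes eliminated by the |lfc| filter: {self.salient_counts['eliminated']}",
            f"MEGs: {self.meg_counts['megs']} ({self.meg_counts['up']} up, "
            f"{self.meg_counts['down']} down); significant: "
            f"{self.meg_counts['significant_megs']}",
            f"progression-significant genes: {len(self.progression)}",
            f"diagnostic feature space: {len(self.feature_panel)} genes",
        ]
        return "\n".join(lines)


def run_stagewise_analysis(
    ds: AnnotatedExpression,
    sd_threshold: float = 1.0,
    lfc_threshold: float = 2.0,
    alpha_linear: float = 1e-5,
    alpha_control: float = 1e-3,
    alpha_between: float = 0.05,
    alpha_meg: float = 0.05,
    top_k: int = 10,
    stage3_cutoff: float = 1.25e-4,
    linear_top_n: int = 10,
    monotone_top_n: int = 200,
    values_are_log2: bool = True,
) -> PipelineResults:
    """Run the full discovery pipeline on an annotated dataset.

    ``values_are_log2`` controls the antilog step: log2-scale input is
    converted to pseudo-counts before the precision-weight transform;
    count-scale input is used as-is.
    """
    filtered, report = apply_filters(ds, sd_threshold=sd_threshold)
    counts = to_pseudocounts(filtered.values) if values_are_log2 else filtered.values
    stages = filtered.stage

    design_baseline = build_design(stages, "baseline")
    vr = voom_transform(counts, design_baseline)

    baseline = StageLinearModel(vr, stages, mode="baseline").fit()
    linear_table = summarize_linear_top(baseline, alpha=alpha_linear)

    cellmeans = StageLinearModel(vr, stages, mode="cellmeans").fit()
    contrast_sc = sal.apply_contrasts(
        cellmeans, sal.make_contrast_matrix("stage_vs_control")
    )
    contrast_between = sal.apply_contrasts(
        cellmeans, sal.make_contrast_matrix("between_stages")
    )

    records = sal.assign_stage_specificity(contrast_sc, lfc_threshold=lfc_threshold)
    records = sal.salience_filter(
        records, contrast_sc, contrast_between,
        alpha_control=alpha_control, alpha_between=alpha_between,
    )
    counts_by_stage = sal.salient_counts(records)
    stage_tables = sal.top_stage_table(records, k=top_k, stage3_cutoff=stage3_cutoff)

    monotone_records = MonotoneTrendModel(vr, stages).fit(alpha=alpha_meg)
    progression = intersect_progression(monotone_records, records)

    salient_genes = [
        g for s, t in stage_tables.items() for g in t.index
    ]
    linear_top_genes = list(linear_table.index[:linear_top_n])
    lin_mono = linear_monotone_overlap(
        monotone_records, linear_table, top_n=monotone_top_n
    )
    panel = assemble_feature_space(salient_genes, linear_top_genes, lin_mono)

    return PipelineResults(
        dataset=filtered,
        filter_report=report,
        voom=vr,
        baseline=baseline,
        cellmeans=cellmeans,
        contrast_sc=contrast_sc,
        contrast_between=contrast_between,
        linear_table=linear_table,
        salience_records=records,
        salient_counts=counts_by_stage,
        stage_tables=stage_tables,
        monotone_records=monotone_records,
        meg_counts=meg_counts(monotone_records),
        progression=progression,
        feature_panel=panel,
    )
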