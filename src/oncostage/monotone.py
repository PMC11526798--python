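"""Monotone expression trends across stages and progression-significant genes.

Treating the stage as a numeric covariate X in {0..4} (control -> 0), each
gene is fitted with a weighted straight line ``y = a X + b``; the slope's
moderated p-value is BH-adjusted across genes. Independently, a gene is
called monotonically up- (down-) regulated when its five group means are
strictly increasing (decreasing) -- strict inequality, no tolerance.
Significant monotone genes (MEGs) intersected with stage-salient genes give
the progression-significant set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GROUPS, STAGE_INDEX, OncostageError
from .linmod import adjust_bh, ebayes_moderate, fit_gene_models
from .voom import VoomResult


def _numeric_design(stages) -> pd.DataFrame:
    stages = pd.Series(list(stages))
    unknown = set(stages) - set(GROUPS)
    if unknown:
        raise OncostageError(f"unknown stage labels: {sorted(unknown)}")
    x = stages.map(STAGE_INDEX).to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise OncostageError("need at least 2 distinct stage values to fit a slope")
    X = pd.DataFrame({"intercept": np.ones_like(x), "stage_index": x})
    X.attrs["mode"] = "numeric"
    return X


def fit_numeric_model(
    vr: VoomResult | tuple[pd.DataFrame, pd.DataFrame | None], stages
) -> pd.DataFrame:
    """Per-gene weighted slope on the numeric stage coding.

    Returns one row per gene: ``slope`` (log2 units per stage step),
    ``intercept``, the moderated two-sided ``p`` for the slope and its
    BH-adjusted value ``adj_p``.
    """
    design = _numeric_design(stages)
    fits = fit_gene_models(vr, design)
    mfit = ebayes_moderate(fits, f_coefs=())
    out = pd.DataFrame(
        {
            "slope": mfit.coefficients["stage_index"],
            "intercept": mfit.coefficients["intercept"],
            "p": mfit.p_t["stage_index"],
        }
    )
    out["adj_p"] = adjust_bh(out["p"])
    return out


class MonotoneTrendModel:
    """Numeric-stage trend model in the Model/Results idiom.

    ``fit()`` returns the per-gene slope table from
    :func:`fit_numeric_model` merged with the strict-monotonicity call on
    the group means of the same matrix.
    """

    def __init__(self, data, stages):
        self.data = data
        self.stages = list(stages)

    def fit(self, alpha: float = 0.05) -> pd.DataFrame:
        logcpm = self.data.logcpm if isinstance(self.data, VoomResult) else self.data[0]
        tab = fit_numeric_model(self.data, self.stages)
        means = group_means(logcpm, self.stages)
        direction = means.apply(
            lambda row: detect_monotone_direction(row.to_numpy()), axis=1
        )
        return select_significant_megs(tab, direction, alpha=alpha)


def group_means(logcpm: pd.DataFrame, stages) -> pd.DataFrame:
    """Unweighted per-group means of the logCPM matrix (genes x 5 groups)."""
    stages = pd.Series(list(stages), index=logcpm.columns)
    cols = {}
    for g in GROUPS:
        sel = stages == g
        if not sel.any():
            raise OncostageError(f"no samples in group {g!r}")
        cols[g] = logcpm.loc[:, sel.to_numpy()].mean(axis=1)
    return pd.DataFrame(cols)


def detect_monotone_direction(means) -> str:
    """Strict ordering call on the five group means: 'up', 'down' or 'none'."""
    m = np.asarray(means, dtype=float)
    if m.shape != (len(GROUPS),):
        raise OncostageError(f"expected {len(GROUPS)} group means, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise OncostageError("group means must be finite")
    d = np.diff(m)
    if np.all(d > 0):
        return "up"
    if np.all(d < 0):
        return "down"
    return "none"


def select_significant_megs(
    fit_table: pd.DataFrame, directions: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Combine slope statistics with monotonicity calls.

    Adds ``direction``, ``is_meg`` (strictly monotone either way) and
    ``significant_meg`` (monotone and ``adj_p < alpha``).
    """
    rec = fit_table.copy()
    rec["direction"] = directions.reindex(rec.index)
    rec["is_meg"] = rec["direction"].isin(["up", "down"])
    rec["significant_meg"] = rec["is_meg"] & (rec["adj_p"] < alpha)
    return rec


def meg_counts(records: pd.DataFrame) -> pd.Series:
    """MEG bookkeeping: up/down/total and the significant subset."""
    return pd.Series(
        {
            "up": int((records["direction"] == "up").sum()),
            "down": int((records["direction"] == "down").sum()),
            "megs": int(records["is_meg"].sum()),
            "significant_megs": int(records["significant_meg"].sum()),
        }
    )


def intersect_progression(
    meg_records: pd.DataFrame, salient_records: pd.DataFrame
) -> pd.DataFrame:
    """Progression-significant genes: significant MEGs that are stage-salient.

    Both tables must cover the same gene universe. The result mirrors the
    reporting layout: gene, assigned stage, UP/DOWN status from the monotone
    direction, and the numeric-model adjusted p; sorted upregulated-first,
    then by adjusted p.
    """
    if set(meg_records.index) != set(salient_records.index):
        raise OncostageError("monotone and salience tables cover different gene universes")
    both = meg_records["significant_meg"] & salient_records["stage_salient"]
    genes = meg_records.index[both]
    out = pd.DataFrame(
        {
            "stage": salient_records.loc[genes, "assigned_stage"],
            "status": meg_records.loc[genes, "direction"].str.upper(),
            "adj_p": meg_records.loc[genes, "adj_p"],
        }
    )
    out["_down"] = (out["status"] == "DOWN").astype(int)
    out = out.sort_values(["_down", "adj_p"]).drop(columns="_down")
    return out


def linear_monotone_overlap(
    meg_records: pd.DataFrame, linear_table: pd.DataFrame, top_n: int = 200
) -> list[str]:
    """Significant MEGs among the top-``top_n`` linear-model genes.

    ``linear_table`` must already be ranked by adjusted F p-value (the
    output of ``summarize_linear_top``). Used as the third component of the
    diagnostic feature space.
    """
    sig = set(meg_records.index[meg_records["significant_meg"]])
    return [g for g in linear_table.index[:top_n] if g in sig]
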