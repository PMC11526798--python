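"""Stage-salience analysis: contrasts, specificity assignment and filtering.

A gene is *stage-specific* when its maximal stage-vs-control log fold-change
exceeds a threshold (default |lfc| > 2); it is assigned to the argmax stage.
It is *stage-salient* when, additionally,

(i)        the BH-adjusted p of its assigned-stage-vs-control contrast is
           below ``alpha_control`` (default 0.001), and
(ii)-(iv)  the three raw between-stage contrast p-values involving the
           assigned stage are all below ``alpha_between`` (default 0.05).

For sparsely populated stages the ``pval_pdt`` statistic -- the product of
the three between-stage p-values for the assigned stage -- provides a total
ranking used to fill per-stage top-k lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GROUPS, STAGES, OncostageError
from .linmod import ContrastResults, ModeratedFitResults

#: Between-stage contrast columns in canonical order.
BETWEEN_PAIRS: tuple[tuple[str, str], ...] = (
    ("I", "II"), ("I", "III"), ("II", "III"), ("I", "IV"), ("II", "IV"), ("III", "IV"),
)


def _pair_name(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def make_contrast_matrix(kind: str) -> pd.DataFrame:
    """Literal contrast matrices over the coefficients (control, I..IV).

    ``stage_vs_control``: one column per stage; -1 on the control row, +1 on
    the stage row. ``between_stages``: six columns, one per ordered stage
    pair (I,II), (I,III), (II,III), (I,IV), (II,IV), (III,IV); -1 on the
    first-listed stage, +1 on the second, 0 on control.
    """
    rows = list(GROUPS)
    if kind == "stage_vs_control":
        C = pd.DataFrame(0.0, index=rows, columns=list(STAGES))
        for s in STAGES:
            C.loc["control", s] = -1.0
            C.loc[s, s] = 1.0
    elif kind == "between_stages":
        cols = [_pair_name(a, b) for a, b in BETWEEN_PAIRS]
        C = pd.DataFrame(0.0, index=rows, columns=cols)
        for (a, b), col in zip(BETWEEN_PAIRS, cols):
            C.loc[a, col] = -1.0
            C.loc[b, col] = 1.0
    else:
        raise OncostageError(
            f"unknown contrast kind {kind!r}; use 'stage_vs_control' or 'between_stages'"
        )
    return C


def apply_contrasts(mfit: ModeratedFitResults, C: pd.DataFrame) -> ContrastResults:
    """Propagate a cell-means moderated fit through a contrast matrix.

    Thin wrapper over :meth:`ModeratedFitResults.contrasts`; requires the
    contrast rows to match the model coefficients exactly.
    """
    return mfit.contrasts(C)


# ---------------------------------------------------------------------------
# specificity and salience
# ---------------------------------------------------------------------------

def assign_stage_specificity(
    cfit_sc: ContrastResults, lfc_threshold: float = 2.0
) -> pd.DataFrame:
    """Assign each gene to the stage with maximal |lfc|, if above threshold.

    Returns one record per gene with the four stage-vs-control lfc values,
    the assigned stage (missing when no stage passes ``|lfc| > threshold``),
    and the ``stage_specific`` flag. Ties on |lfc| resolve to the earliest
    stage.
    """
    missing = [s for s in STAGES if s not in cfit_sc.lfc.columns]
    if missing:
        raise OncostageError(f"stage-vs-control fit lacks contrasts: {missing}")
    lfc = cfit_sc.lfc[list(STAGES)]
    abs_lfc = lfc.abs()
    max_abs = abs_lfc.max(axis=1)
    # idxmax returns the first column on ties; column order is I..IV
    argmax = abs_lfc.idxmax(axis=1)
    specific = max_abs > lfc_threshold
    rec = pd.DataFrame({f"lfc_{s}": lfc[s] for s in STAGES})
    rec["max_abs_lfc"] = max_abs
    rec["assigned_stage"] = argmax.where(specific, other=pd.NA)
    rec["stage_specific"] = specific
    return rec


def compute_pval_pdt(record: pd.Series | str, cfit_between: ContrastResults,
                     assigned_stage: str | None = None) -> float:
    """Product of the three between-stage p-values for the assigned stage.

    ``record`` may be a row from :func:`assign_stage_specificity` (with its
    gene id as ``record.name``) or a gene id with ``assigned_stage`` given
    explicitly.
    """
    if isinstance(record, pd.Series):
        gene = record.name
        stage = record["assigned_stage"]
    else:
        gene, stage = record, assigned_stage
    if pd.isna(stage):
        raise OncostageError(f"gene {gene!r} has no assigned stage")
    ps = _between_pvals_for_stage(cfit_between, str(stage)).loc[gene]
    if ps.isna().any():
        raise OncostageError(f"missing between-stage p-value for gene {gene!r}")
    return float(ps.prod())


def _between_pvals_for_stage(cfit_between: ContrastResults, stage: str) -> pd.DataFrame:
    """The three raw between-stage p-value columns involving ``stage``."""
    cols = [_pair_name(a, b) for a, b in BETWEEN_PAIRS if stage in (a, b)]
    missing = [c for c in cols if c not in cfit_between.p.columns]
    if missing:
        raise OncostageError(f"between-stage fit lacks contrasts: {missing}")
    return cfit_between.p[cols]


def salience_filter(
    records: pd.DataFrame,
    cfit_sc: ContrastResults,
    cfit_between: ContrastResults,
    alpha_control: float = 0.001,
    alpha_between: float = 0.05,
    adjust_between: bool = False,
) -> pd.DataFrame:
    """Apply the four-pronged salience criteria to stage-specific genes.

    Adds, per gene with an assigned stage: the BH-adjusted p of the
    assigned-stage-vs-control contrast, the three between-stage p-values
    involving that stage (raw by default; ``adjust_between=True`` switches
    criteria (ii)-(iv) to BH-adjusted values), their product ``pval_pdt``,
    and the ``stage_salient`` flag.
    """
    rec = records.copy()
    rec["adj_p_control"] = np.nan
    for k in (1, 2, 3):
        rec[f"p_between_{k}"] = np.nan
    rec["pval_pdt"] = np.nan
    rec["stage_salient"] = False

    between_p = cfit_between.p_adj if adjust_between else cfit_between.p
    for stage in STAGES:
        mask = rec["assigned_stage"] == stage
        if not mask.any():
            continue
        genes = rec.index[mask]
        rec.loc[genes, "adj_p_control"] = cfit_sc.p_adj.loc[genes, stage]
        cols = [_pair_name(a, b) for a, b in BETWEEN_PAIRS if stage in (a, b)]
        pvals = between_p.loc[genes, cols]
        for k, c in enumerate(cols, start=1):
            rec.loc[genes, f"p_between_{k}"] = pvals[c]
        rec.loc[genes, "pval_pdt"] = pvals.prod(axis=1)
        rec.loc[genes, "stage_salient"] = (
            (rec.loc[genes, "adj_p_control"] < alpha_control)
            & (pvals < alpha_between).all(axis=1)
        )
    return rec


def salient_counts(records: pd.DataFrame) -> pd.Series:
    """Number of stage-salient genes per stage (plus eliminated count)."""
    out = {}
    for s in STAGES:
        out[s] = int(
            ((records["assigned_stage"] == s) & records["stage_salient"]).sum()
        )
    out["eliminated"] = int((~records["stage_specific"]).sum())
    return pd.Series(out)


def top_stage_table(
    records: pd.DataFrame,
    k: int = 10,
    stage3_cutoff: float | None = 1.25e-4,
) -> dict[str, pd.DataFrame]:
    """Per-stage candidate tables combining strict salience with pval_pdt fill.

    For each stage: salient genes ranked by the adjusted stage-vs-control p
    come first. Stages with at least ``k`` salient genes report them all
    (the first ``k`` flagged ``in_top_k``). Sparse stages are filled to ``k``
    with the lowest-``pval_pdt`` stage-specific genes. Stage III follows a
    cutoff rule instead of a fixed fill: every stage-III-specific gene with
    ``pval_pdt`` below ``stage3_cutoff`` is reported (still filled to ``k``
    if even the cutoff yields fewer).

    Each table carries a ``source`` column: ``salient`` or ``pval_pdt_fill``.
    """
    if "pval_pdt" not in records.columns:
        raise OncostageError("records lack pval_pdt; run salience_filter first")
    out: dict[str, pd.DataFrame] = {}
    for stage in STAGES:
        here = records[records["assigned_stage"] == stage]
        sal = here[here["stage_salient"]].sort_values("adj_p_control")
        pool = here[~here["stage_salient"]].sort_values("pval_pdt")
        sal = sal.assign(source="salient")
        if stage == "III" and stage3_cutoff is not None:
            fill = pool[pool["pval_pdt"] < stage3_cutoff]
            if len(sal) + len(fill) < k:
                fill = pool.head(k - len(sal))
        elif len(sal) >= k:
            fill = pool.iloc[0:0]
        else:
            fill = pool.head(k - len(sal))
        fill = fill.assign(source="pval_pdt_fill")
        tab = pd.concat([sal, fill])
        tab["in_top_k"] = np.arange(len(tab)) < k
        out[stage] = tab
    return out


def augmented_stage_sets(tables: dict[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Gene lists per stage from :func:`top_stage_table` (fallback-augmented)."""
    return {s: list(t.index) for s, t in tables.items()}
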