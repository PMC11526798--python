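"""Survival risk modelling: Cox screening, backward-AIC panels, KM stratification.

Candidate genes are screened by univariate Cox proportional-hazards fits on
continuous log2 expression (partial likelihood, Efron tie handling); the
significant ones seed a multivariate model pruned by backward selection on
the partial AIC. The resulting linear risk score
``sum_i beta_i * expression_i`` is thresholded (median by default) to split
patients into high- and low-risk groups, evaluated by Kaplan-Meier curves
with Greenwood 95% bands, the two-group log-rank test and Harrell's
concordance index (with a seeded bootstrap for its uncertainty).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_cindex

from .datatypes import OncostageError


def _check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise OncostageError(f"survival table lacks column {col!r}")
    if (surv["time"] < 0).any():
        raise OncostageError("negative survival times")
    if not surv["event"].isin([0, 1]).all():
        raise OncostageError("event must be 0/1")
    return surv


def _cox_fit(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def univariate_cox_screen(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    genes=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene univariate Cox fits on continuous expression.

    ``expr`` is samples x genes, row-aligned with ``surv`` (``time``,
    ``event``). Returns beta, hazard ratio, standard error and p per gene
    with a ``significant`` flag at ``p < alpha``. Genes whose fit fails to
    converge are excluded with a warning.
    """
    surv = _check_survival(surv)
    if int(surv["event"].sum()) < 2:
        raise OncostageError("need at least 2 events for Cox screening")
    genes = list(genes) if genes is not None else list(expr.columns)
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise OncostageError(f"genes missing from expression: {missing[:5]}")
    rows = {}
    for g in genes:
        df = surv[["time", "event"]].copy()
        df["x"] = expr.loc[df.index, g].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = _cox_fit(df)
        except (ConvergenceError, ValueError) as err:
            warnings.warn(f"Cox fit failed for gene {g!r}: {err}; excluded")
            continue
        rows[g] = {
            "beta": float(cph.params_["x"]),
            "hazard_ratio": float(np.exp(cph.params_["x"])),
            "se": float(cph.standard_errors_["x"]),
            "p": float(cph.summary.loc["x", "p"]),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if len(out):
        out["significant"] = out["p"] < alpha
    return out


@dataclass
class RiskModel:
    """A fitted linear risk score over a gene panel.

    ``score = sum_i beta_i * expression_i``; ``threshold`` (set from the
    training score distribution) splits patients into high (> threshold)
    and low (<= threshold) risk.
    """

    genes: tuple[str, ...]
    betas: pd.Series
    gene_p: pd.Series
    model_p: float
    concordance: float
    threshold: float | None = None
    aic: float = field(default=np.nan)

    def score(self, expressions) -> pd.Series | float:
        return compute_risk_score(self, expressions)

    def summary(self) -> str:
        lines = [
            "Cox risk-score model",
            "=" * 40,
            "risk score = "
            + " + ".join(f"{b:.5g} * {g}" for g, b in self.betas.items()),
            f"model p-value (LR test): {self.model_p:.3g}",
            f"concordance index:       {self.concordance:.3f}",
        ]
        if self.threshold is not None:
            lines.append(f"risk threshold:          {self.threshold:.4g}")
        for g in self.genes:
            lines.append(f"  {g:<12s} beta={self.betas[g]:+.4f}  p={self.gene_p[g]:.3g}")
        return "\n".join(lines)


def fit_cox_backward_aic(
    expr: pd.DataFrame, surv: pd.DataFrame, candidates
) -> RiskModel:
    """Backward selection on the partial AIC from the full multivariate fit.

    At each step the term whose removal most decreases the AIC is dropped;
    selection stops when no removal decreases it. Dropping the last term is
    allowed when the null model's AIC is lower, in which case the returned
    model is empty (with a warning).
    """
    surv = _check_survival(surv)
    candidates = list(candidates)
    if not candidates:
        raise OncostageError("empty candidate set")
    n_events = int(surv["event"].sum())
    if n_events < len(candidates):
        warnings.warn(
            f"{n_events} events for {len(candidates)} candidates; "
            "selection may be unstable"
        )

    def fit_subset(genes: list[str]) -> tuple[CoxPHFitter | None, float]:
        if not genes:
            # null model: partial AIC with zero parameters
            full = _fit_or_raise(candidates)
            ll0 = full.log_likelihood_ - full.log_likelihood_ratio_test().test_statistic / 2.0
            return None, -2.0 * ll0
        cph = _fit_or_raise(genes)
        return cph, float(cph.AIC_partial_)

    def _fit_or_raise(genes: list[str]) -> CoxPHFitter:
        df = surv[["time", "event"]].copy()
        for g in genes:
            df[g] = expr.loc[df.index, g].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _cox_fit(df)

    current = sorted(candidates)  # input-order independent
    cph, aic = fit_subset(current)
    while current:
        best_drop, best_aic, best_fit = None, aic, cph
        for g in current:
            reduced = [x for x in current if x != g]
            try:
                cand_fit, cand_aic = fit_subset(reduced)
            except (ConvergenceError, ValueError):
                continue
            if cand_aic < best_aic - 1e-10:
                best_drop, best_aic, best_fit = g, cand_aic, cand_fit
        if best_drop is None:
            break
        current = [x for x in current if x != best_drop]
        cph, aic = best_fit, best_aic

    if not current or cph is None:
        warnings.warn("backward AIC selection removed every candidate")
        return RiskModel(
            genes=(), betas=pd.Series(dtype=float), gene_p=pd.Series(dtype=float),
            model_p=np.nan, concordance=np.nan, aic=aic,
        )
    return RiskModel(
        genes=tuple(current),
        betas=cph.params_.reindex(current),
        gene_p=cph.summary["p"].reindex(current),
        model_p=float(cph.log_likelihood_ratio_test().p_value),
        concordance=float(cph.concordance_index_),
        aic=aic,
    )


def compute_risk_score(model: RiskModel, expressions) -> pd.Series | float:
    """Linear risk score ``sum_i beta_i * expression_i``.

    ``expressions`` is either a samples x genes frame (returns a Series) or
    a single gene -> value mapping/Series (returns a float). Missing model
    genes are a hard error.
    """
    if isinstance(expressions, pd.DataFrame):
        missing = [g for g in model.genes if g not in expressions.columns]
        if missing:
            raise OncostageError(f"missing model gene(s): {missing}")
        vals = expressions[list(model.genes)].to_numpy(dtype=float)
        score = vals @ model.betas.reindex(list(model.genes)).to_numpy()
        return pd.Series(score, index=expressions.index, name="risk_score")
    row = expressions if isinstance(expressions, pd.Series) else pd.Series(dict(expressions))
    missing = [g for g in model.genes if g not in row.index]
    if missing:
        raise OncostageError(f"missing model gene(s): {missing}")
    return float(
        row[list(model.genes)].to_numpy(dtype=float)
        @ model.betas.reindex(list(model.genes)).to_numpy()
    )


# ---------------------------------------------------------------------------
# stratification and evaluation
# ---------------------------------------------------------------------------

@dataclass
class StratificationResult:
    """Risk groups with their Kaplan-Meier estimates and the log-rank test."""

    threshold: float
    groups: pd.Series  # "high" / "low"
    km_tables: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    fitters: dict[str, KaplanMeierFitter]

    def plot(self, ax=None):
        """Overlayed KM curves with 95% bands (matplotlib axes)."""
        for name, kmf in self.fitters.items():
            ax = kmf.plot_survival_function(ax=ax, label=f"{name} risk")
        return ax


def stratify_and_km(
    scores: pd.Series,
    surv: pd.DataFrame,
    threshold_rule: str = "median",
    threshold: float | None = None,
) -> StratificationResult:
    """Split on the risk score and estimate per-group survival.

    ``threshold_rule``: ``"median"`` takes the median of the supplied
    scores; ``"value"`` uses the explicit ``threshold``. High risk is a
    score strictly above the threshold (scores exactly at the threshold go
    to the low-risk group).
    """
    surv = _check_survival(surv)
    scores = scores.reindex(surv.index)
    if scores.isna().any():
        raise OncostageError("scores missing for some survival records")
    if threshold_rule == "median":
        thr = float(scores.median())
    elif threshold_rule == "value":
        if threshold is None:
            raise OncostageError("threshold_rule='value' requires a threshold")
        thr = float(threshold)
    else:
        raise OncostageError("threshold_rule must be 'median' or 'value'")
    groups = pd.Series(np.where(scores > thr, "high", "low"), index=scores.index)
    sizes = groups.value_counts()
    for name in ("high", "low"):
        if sizes.get(name, 0) < 2:
            raise OncostageError(f"{name}-risk group has fewer than 2 samples")
    chi2, p = logrank_test(surv, groups)

    fitters: dict[str, KaplanMeierFitter] = {}
    km_tables: dict[str, pd.DataFrame] = {}
    for name in ("high", "low"):
        sel = groups == name
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[sel, "time"], surv.loc[sel, "event"], label=name)
        fitters[name] = kmf
        tab = kmf.survival_function_.copy()
        tab.columns = ["survival"]
        ci = kmf.confidence_interval_
        tab["ci_lower"] = ci.iloc[:, 0].to_numpy()
        tab["ci_upper"] = ci.iloc[:, 1].to_numpy()
        km_tables[name] = tab
    return StratificationResult(
        threshold=thr, groups=groups, km_tables=km_tables,
        logrank_chi2=chi2, logrank_p=p, fitters=fitters,
    )


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) on 1 df."""
    surv = _check_survival(surv)
    groups = groups.reindex(surv.index)
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise OncostageError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    if int(surv["event"].sum()) < 1:
        raise OncostageError("log-rank test undefined without events")
    a = groups == labels[0]
    res = _ll_logrank(
        surv.loc[a.to_numpy(), "time"], surv.loc[(~a).to_numpy(), "time"],
        surv.loc[a.to_numpy(), "event"], surv.loc[(~a).to_numpy(), "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def concordance_index(scores: pd.Series, surv: pd.DataFrame) -> float:
    """Harrell's C: fraction of usable pairs where the higher-risk sample
    has the shorter observed survival (score ties count 0.5)."""
    surv = _check_survival(surv)
    scores = scores.reindex(surv.index)
    try:
        return float(
            _ll_cindex(surv["time"], -scores.to_numpy(), surv["event"])
        )
    except ZeroDivisionError as err:
        raise OncostageError("no comparable pairs for the concordance index") from err


def bootstrap_concordance(
    scores: pd.Series, surv: pd.DataFrame, n_boot: int = 200, seed: int = 42
) -> tuple[float, float]:
    """Concordance index with a bootstrap standard deviation (seeded)."""
    c = concordance_index(scores, surv)
    rng = np.random.default_rng(seed)
    n = len(surv)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        s = scores.iloc[idx].reset_index(drop=True)
        sv = surv.iloc[idx].reset_index(drop=True)
        try:
            draws.append(concordance_index(s, sv))
        except OncostageError:
            continue
    sd = float(np.std(draws, ddof=1)) if len(draws) > 1 else float("nan")
    return c, sd
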