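"""Stagewise linear models with empirical-Bayes moderated statistics.

Each gene's (voom-transformed, precision-weighted) expression is fitted
against one of two design matrices over the five sample groups
(control, stages I-IV):

* ``baseline`` -- intercept alpha plus four stage indicators; the stage
  coefficients beta_1..beta_4 are log2 fold-changes relative to control.
* ``cellmeans`` -- five group indicators, no intercept; each coefficient is
  the (weighted) group mean, the natural parameterisation for contrasts.

Per-gene residual variances are shrunk toward a pooled prior (df d0,
variance s0^2) estimated by the standard moments method on log variances,
yielding moderated t and F statistics on d0 + df degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GROUPS, STAGES, OncostageError
from .voom import VoomResult

_CHUNK = 4096  # genes per batch in the WLS sweep


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(stages, mode: str) -> pd.DataFrame:
    """Build the samples x coefficients design matrix.

    ``baseline`` mode: columns (intercept, I, II, III, IV) where the
    intercept is all ones and stage columns are indicators.
    ``cellmeans`` mode: columns (control, I, II, III, IV), one indicator per
    group, no intercept (each row sums to one).
    """
    stages = pd.Series(list(stages))
    unknown = set(stages) - set(GROUPS)
    if unknown:
        raise OncostageError(f"unknown stage labels: {sorted(unknown)}")
    if len(stages) == 0:
        raise OncostageError("no samples")
    if mode == "baseline":
        cols = {"intercept": np.ones(len(stages))}
        for s in STAGES:
            cols[s] = (stages == s).to_numpy(dtype=float)
    elif mode == "cellmeans":
        cols = {g: (stages == g).to_numpy(dtype=float) for g in GROUPS}
    else:
        raise OncostageError(f"unknown design mode {mode!r}; use 'baseline' or 'cellmeans'")
    X = pd.DataFrame(cols)
    X.attrs["mode"] = mode
    return X


# ---------------------------------------------------------------------------
# per-gene weighted least squares
# ---------------------------------------------------------------------------

@dataclass
class GeneFitCollection:
    """Per-gene WLS estimates sharing one design.

    ``cov_unscaled`` holds the per-gene (X'WX)^-1 matrices; multiplying by
    the (moderated) residual variance gives coefficient covariances.
    """

    coefficients: pd.DataFrame  # genes x coefficients
    stdev_unscaled: pd.DataFrame  # genes x coefficients, sqrt diag of (X'WX)^-1
    sigma2: pd.Series  # residual variance per gene
    df_residual: int
    cov_unscaled: np.ndarray  # genes x p x p
    design: pd.DataFrame
    mode: str = "baseline"


def fit_gene_models(
    vr: VoomResult | tuple[pd.DataFrame, pd.DataFrame | None],
    design: pd.DataFrame,
) -> GeneFitCollection:
    """Fit the per-gene weighted least-squares model.

    Parameters
    ----------
    vr : VoomResult or (logcpm, weights)
        Expression matrix and optional per-observation precision weights
        (``None`` weights means ordinary least squares).
    design : pandas.DataFrame
        Samples x coefficients design (from :func:`build_design`).
    """
    if isinstance(vr, VoomResult):
        Y, W = vr.logcpm, vr.weights
    else:
        Y, W = vr
    Yv = Y.to_numpy(dtype=float)
    G, n = Yv.shape
    X = design.to_numpy(dtype=float)
    p = X.shape[1]
    if X.shape[0] != n:
        raise OncostageError(f"design has {X.shape[0]} rows for {n} samples")
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns: those whose removal restores full rank
        bad = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1))
            == np.linalg.matrix_rank(X)
        ]
        raise OncostageError(f"rank-deficient design; collinear columns: {bad}")
    if n <= p:
        raise OncostageError(f"residual df would be {n - p}; need n_samples > n_coefficients")

    if W is None:
        Wv = np.ones_like(Yv)
    else:
        Wv = W.to_numpy(dtype=float)
        if np.any(Wv <= 0):
            raise OncostageError("weights must be strictly positive")

    beta = np.empty((G, p))
    cov = np.empty((G, p, p))
    sigma2 = np.empty(G)
    df = n - p
    for start in range(0, G, _CHUNK):
        sl = slice(start, min(start + _CHUNK, G))
        w = Wv[sl]  # g x n
        y = Yv[sl]
        Xw = w[:, :, None] * X[None, :, :]  # g x n x p
        XtWX = np.einsum("np,gnq->gpq", X, Xw)
        XtWy = np.einsum("np,gn->gp", X, w * y)
        c = np.linalg.inv(XtWX)
        b = np.einsum("gpq,gq->gp", c, XtWy)
        resid = y - b @ X.T
        sigma2[sl] = np.einsum("gn,gn->g", w, resid**2) / df
        beta[sl] = b
        cov[sl] = c

    se_unscaled = np.sqrt(np.einsum("gpp->gp", cov))
    mode = design.attrs.get("mode", "baseline")
    return GeneFitCollection(
        coefficients=pd.DataFrame(beta, index=Y.index, columns=design.columns),
        stdev_unscaled=pd.DataFrame(se_unscaled, index=Y.index, columns=design.columns),
        sigma2=pd.Series(sigma2, index=Y.index, name="sigma2"),
        df_residual=df,
        cov_unscaled=cov,
        design=design,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 75) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise OncostageError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(
    sigma2: np.ndarray, df: float, zero_floor: float = 0.0
) -> tuple[float, float]:
    """Moments estimate of the variance prior (d0, s0^2) on log variances.

    Matches the scaled-F model for sample variances: log s^2 has mean
    ``digamma(df/2) - log(df/2) + log(s0^2) + (prior terms)`` and excess
    variance ``trigamma(d0/2)``; the latter is inverted by Newton iteration.
    Returns ``d0 = inf`` when the observed spread is no larger than expected
    under a single common variance.
    """
    s2 = np.asarray(sigma2, dtype=float)
    # exact interpolation leaves ~1e-30 float dust rather than true zeros;
    # zero_floor (set by the caller from the data scale) catches it
    pos = s2 > max(np.max(s2, initial=0.0) * 1e-12, zero_floor)
    if pos.sum() < 2:
        warnings.warn("all residual variances are zero; prior df set to infinity")
        return np.inf, 0.0
    if not pos.all():
        warnings.warn(f"{(~pos).sum()} genes with zero residual variance excluded "
                      "from prior estimation")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def adjust_bh(pvals) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment.

    Missing values propagate as missing without affecting the ranks of the
    finite entries. Values outside [0, 1] are a hard error.
    """
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if vals.size and (np.any(vals < 0) or np.any(vals > 1)):
        raise OncostageError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index, name=pvals.name)
    return out


@dataclass
class ModeratedFitResults:
    """Moderated per-gene statistics for one fitted design.

    Carries the WLS estimates plus the shared moderation parameters
    (prior df ``d0``, prior variance ``s02``), posterior variances, and the
    moderated t (per coefficient) and F (over ``f_coefs``) statistics with
    raw and BH-adjusted p-values.
    """

    fits: GeneFitCollection
    d0: float
    s02: float
    s2_post: pd.Series
    t: pd.DataFrame
    p_t: pd.DataFrame
    f_coefs: tuple[str, ...]
    F: pd.Series | None
    p_F: pd.Series | None
    p_F_adj: pd.Series | None
    df_total: float = field(init=False)

    def __post_init__(self) -> None:
        self.df_total = min(self.fits.df_residual + self.d0, 1e8)

    # convenience passthroughs ------------------------------------------------
    @property
    def coefficients(self) -> pd.DataFrame:
        return self.fits.coefficients

    @property
    def mode(self) -> str:
        return self.fits.mode

    @property
    def gene_ids(self) -> pd.Index:
        return self.fits.coefficients.index

    def contrasts(self, C: pd.DataFrame) -> "ContrastResults":
        """Propagate the fit through a coefficients x contrasts matrix.

        Estimates are ``C' beta``; unscaled standard errors come from the
        full coefficient covariance ``C' (X'WX)^-1 C``; moderated t and
        p-values are recomputed on the contrast scale and BH-adjusted per
        contrast column across genes.
        """
        fits = self.fits
        if list(C.index) != list(fits.coefficients.columns):
            raise OncostageError(
                f"contrast rows {list(C.index)} do not match model "
                f"coefficients {list(fits.coefficients.columns)}"
            )
        Cv = C.to_numpy(dtype=float)
        est = fits.coefficients.to_numpy() @ Cv
        var_unscaled = np.einsum("gpq,pk,qk->gk", fits.cov_unscaled, Cv, Cv)
        se_unscaled = np.sqrt(np.maximum(var_unscaled, 0.0))
        se = se_unscaled * np.sqrt(self.s2_post.to_numpy())[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
        # zero contrast (or exactly-zero variance with zero estimate): t=0, p=1
        t[(se == 0) & (est == 0)] = 0.0
        p = 2.0 * stats.t.sf(np.abs(t), self.df_total)
        idx, cols = fits.coefficients.index, C.columns
        p_df = pd.DataFrame(p, index=idx, columns=cols)
        p_adj = p_df.apply(adjust_bh, axis=0)
        return ContrastResults(
            lfc=pd.DataFrame(est, index=idx, columns=cols),
            stdev_unscaled=pd.DataFrame(se_unscaled, index=idx, columns=cols),
            t=pd.DataFrame(t, index=idx, columns=cols),
            p=p_df,
            p_adj=p_adj,
            df_total=self.df_total,
            contrast_matrix=C,
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the moderated fit."""
        lines = [
            "Moderated stagewise linear model",
            "=" * 40,
            f"mode:            {self.mode}",
            f"genes:           {len(self.gene_ids)}",
            f"residual df:     {self.fits.df_residual}",
            f"prior df (d0):   {self.d0:.4g}",
            f"prior var (s0^2):{self.s02:.4g}",
            f"total df:        {self.df_total:.4g}",
        ]
        if self.p_F_adj is not None:
            lines.append(f"F-test over:     {', '.join(self.f_coefs)}")
            ranked = self.p_F_adj.sort_values().head(top)
            lines.append(f"top {top} genes by adjusted F p-value:")
            for g, q in ranked.items():
                lines.append(f"  {g:<16s} adj p = {q:.3g}")
        return "\n".join(lines)


@dataclass
class ContrastResults:
    """Moderated statistics on the contrast scale (genes x contrasts)."""

    lfc: pd.DataFrame
    stdev_unscaled: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    df_total: float
    contrast_matrix: pd.DataFrame


def ebayes_moderate(
    fits: GeneFitCollection,
    f_coefs: tuple[str, ...] | None = None,
) -> ModeratedFitResults:
    """Shrink residual variances and compute moderated t/F statistics.

    ``f_coefs`` selects the coefficients jointly tested by the moderated F
    (default: every non-intercept column in baseline mode; no F otherwise).
    """
    if len(fits.sigma2) < 2:
        raise OncostageError("need at least 2 genes for empirical-Bayes moderation")
    df = fits.df_residual
    if df <= 0:
        raise OncostageError("non-positive residual df")
    scale = max(1.0, float(np.abs(fits.coefficients.to_numpy()).max()))
    d0, s02 = estimate_prior(
        fits.sigma2.to_numpy(), df, zero_floor=(1e-10 * scale) ** 2
    )
    s2 = fits.sigma2.to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    s2_post_s = pd.Series(s2_post, index=fits.sigma2.index, name="s2_post")

    df_total = min(df + d0, 1e8)
    se = fits.stdev_unscaled.to_numpy() * np.sqrt(s2_post)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.coefficients.to_numpy() / se
    t = np.where(np.isnan(t), 0.0, t)
    p_t = 2.0 * stats.t.sf(np.abs(t), df_total)
    idx, cols = fits.coefficients.index, fits.coefficients.columns
    t_df = pd.DataFrame(t, index=idx, columns=cols)
    p_df = pd.DataFrame(p_t, index=idx, columns=cols)

    if f_coefs is None:
        f_coefs = tuple(c for c in cols if c != "intercept") if fits.mode == "baseline" else ()
    F = p_F = p_F_adj = None
    if f_coefs:
        missing = [c for c in f_coefs if c not in cols]
        if missing:
            raise OncostageError(f"F-test coefficients not in design: {missing}")
        sel = [list(cols).index(c) for c in f_coefs]
        r = len(sel)
        b = fits.coefficients.to_numpy()[:, sel]
        V = fits.cov_unscaled[np.ix_(range(len(idx)), sel, sel)]
        quad = np.einsum("gp,gp->g", b, np.linalg.solve(V, b[:, :, None])[:, :, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            Fv = quad / (r * s2_post)
        Fv = np.where(np.isnan(Fv), 0.0, Fv)
        pF = stats.f.sf(Fv, r, df_total)
        F = pd.Series(Fv, index=idx, name="F")
        p_F = pd.Series(pF, index=idx, name="p_F")
        p_F_adj = adjust_bh(p_F).rename("p_F_adj")

    return ModeratedFitResults(
        fits=fits, d0=d0, s02=s02, s2_post=s2_post_s,
        t=t_df, p_t=p_df, f_coefs=tuple(f_coefs), F=F, p_F=p_F, p_F_adj=p_F_adj,
    )


# ---------------------------------------------------------------------------
# Model facade
# ---------------------------------------------------------------------------

class StageLinearModel:
    """Per-gene weighted linear model over discrete cancer stages.

    A thin model object in the statsmodels idiom: construct from data,
    call :meth:`fit` to obtain :class:`ModeratedFitResults`.

    Parameters
    ----------
    data : VoomResult or (logcpm, weights)
        Expression and precision weights.
    stages : sequence of str
        Per-sample group labels (control, I-IV), aligned with columns.
    mode : {"baseline", "cellmeans"}
        Design parameterisation.
    """

    def __init__(self, data, stages, mode: str = "baseline"):
        self.data = data
        self.design = build_design(stages, mode)
        self.mode = mode

    def fit(self, f_coefs: tuple[str, ...] | None = None) -> ModeratedFitResults:
        fits = fit_gene_models(self.data, self.design)
        return ebayes_moderate(fits, f_coefs=f_coefs)


# ---------------------------------------------------------------------------
# ranked output
# ---------------------------------------------------------------------------

def summarize_linear_top(mfit: ModeratedFitResults, alpha: float = 1e-5) -> pd.DataFrame:
    """Rank genes of a baseline-mode fit by adjusted F p-value.

    Adds the per-stage log fold-changes, a regulation status (UP if every
    stage coefficient is positive, DOWN if every one is negative, MIXED
    otherwise) and a significance flag at ``adj p < alpha``. Ties in the
    adjusted p are broken by descending max |lfc|, then gene id.
    """
    if mfit.mode != "baseline":
        raise OncostageError("summarize_linear_top requires a baseline-mode fit")
    if mfit.p_F_adj is None:
        raise OncostageError("fit carries no F statistics")
    lfc = mfit.coefficients[list(STAGES)]
    status = np.where(
        (lfc > 0).all(axis=1), "UP", np.where((lfc < 0).all(axis=1), "DOWN", "MIXED")
    )
    tab = lfc.copy()
    tab.columns = [f"lfc_{s}" for s in STAGES]
    tab["sigma2"] = mfit.fits.sigma2
    tab["df_residual"] = mfit.fits.df_residual
    tab["F"] = mfit.F
    tab["p_F"] = mfit.p_F
    tab["p_F_adj"] = mfit.p_F_adj
    tab["status"] = status
    tab["significant"] = tab["p_F_adj"] < alpha
    tab["_maxlfc"] = lfc.abs().max(axis=1)
    tab["_gene"] = tab.index
    tab = tab.sort_values(by=["p_F_adj", "_maxlfc", "_gene"], ascending=[True, False, True])
    return tab.drop(columns=["_maxlfc", "_gene"])
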