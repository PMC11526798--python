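"""Precision weights for count-like expression data (voom transform).

RNA-seq counts are heteroscedastic on the log scale: low-abundance genes are
noisier than high-abundance ones. The voom approach converts counts to
log2 counts-per-million (logCPM), estimates the mean-variance trend by
smoothing per-gene residual standard deviations against average log-count,
and converts the predicted standard deviation of each observation into an
inverse-variance weight for downstream weighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .datatypes import OncostageError

#: Smallest predicted sqrt-standard-deviation; guards 1/sd**4 blow-up.
_MIN_SQRT_SD = 1e-4

#: Below this many genes the trend cannot be estimated reliably.
_MIN_GENES_FOR_TREND = 10


@dataclass
class VoomResult:
    """logCPM matrix, per-observation precision weights and the fitted trend.

    ``trend_x``/``trend_y`` are the smoothed (average log2 count,
    sqrt residual sd) curve; :meth:`trend` evaluates it with constant
    extrapolation beyond the fitted range.
    """

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise OncostageError("voom weights must be strictly positive and finite")
        if not np.all(np.isfinite(self.logcpm.to_numpy())):
            raise OncostageError("logcpm must be finite")

    def trend(self, x) -> np.ndarray:
        """Predicted sqrt residual sd at average log2 count ``x``."""
        return np.interp(x, self.trend_x, self.trend_y)


def voom_transform(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    span: float = 0.5,
) -> VoomResult:
    """Compute logCPM values and inverse-variance precision weights.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative count-like matrix, genes x samples.
    design : pandas.DataFrame
        Full-rank design matrix, samples x coefficients (rows aligned with
        the count columns).
    span : float
        Lowess span for the mean-variance trend.

    Notes
    -----
    logCPM is ``log2((count + 0.5) / (library_size + 1) * 1e6)``. The trend
    is fitted on sqrt residual standard deviations from an unweighted
    per-gene fit, regressed on average log2 count; weights are the inverse
    fourth power of the trend evaluated at each observation's fitted
    log2 count.
    """
    Y = counts.to_numpy(dtype=float)
    if np.any(Y < 0):
        raise OncostageError("counts must be non-negative")
    X = design.to_numpy(dtype=float)
    if X.shape[0] != Y.shape[1]:
        raise OncostageError(
            f"design has {X.shape[0]} rows but counts has {Y.shape[1]} samples"
        )
    lib = Y.sum(axis=0)
    if np.any(lib == 0):
        zero = counts.columns[lib == 0].tolist()
        raise OncostageError(f"samples with zero library size: {zero[:5]}")

    logcpm = np.log2((Y + 0.5) / (lib + 1.0) * 1e6)

    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise OncostageError("design matrix is rank deficient")
    df_resid = n - p
    pinv = np.linalg.pinv(X)  # p x n
    B = logcpm @ pinv.T  # genes x p
    fitted = B @ X.T  # fitted logCPM
    resid = logcpm - fitted
    if df_resid > 0:
        sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    else:
        sigma = np.zeros(Y.shape[0])

    amean = logcpm.mean(axis=1)
    # average log2 count corresponding to the logCPM average
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    flat_reason = None
    if Y.shape[0] < _MIN_GENES_FOR_TREND:
        flat_reason = f"only {Y.shape[0]} genes; need >= {_MIN_GENES_FOR_TREND} for a trend"
    elif np.ptp(sy) < 1e-10:
        flat_reason = "residual variation is constant across genes"

    if flat_reason is not None:
        warnings.warn(f"voom: falling back to constant weights ({flat_reason})")
        W = np.ones_like(logcpm)
        trend_x = np.array([sx.min(), sx.max()]) if len(sx) else np.array([0.0, 1.0])
        trend_y = np.full(2, max(float(sy.mean()) if len(sy) else 1.0, _MIN_SQRT_SD))
    else:
        smoothed = _sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
        trend_x, trend_y = smoothed[:, 0], smoothed[:, 1]
        trend_y = np.maximum(trend_y, _MIN_SQRT_SD)
        # fitted log2 count per observation, then sd prediction -> weight
        fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
        pred_sqrt_sd = np.interp(fitted_logcount, trend_x, trend_y)
        W = 1.0 / pred_sqrt_sd**4

    return VoomResult(
        logcpm=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(W, index=counts.index, columns=counts.columns),
        trend_x=np.asarray(trend_x, dtype=float),
        trend_y=np.asarray(trend_y, dtype=float),
    )
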