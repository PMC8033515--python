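"""Mean-variance trend estimation and per-observation precision weights.

Counts transformed to log2-cpm have a variance that depends on abundance.
Per gene, an ordinary least-squares fit on the analysis design gives a
residual standard deviation s_g and an average log2-count r_g; a locally
weighted regression of sqrt(s_g) on r_g captures the mean-variance trend.
Each observation's weight is the predicted sqrt-standard-deviation at its
fitted log2-count raised to the power -4, i.e. an inverse-variance weight
for the log2-cpm scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger("dystromon")

#: Predicted sqrt-sd floor before the -4th power; caps weights for
#: degenerate zero-variance genes.
SQRT_SD_FLOOR = 1e-3


@dataclass(frozen=True)
class Trend:
    grid: np.ndarray        # average log2-count values (increasing)
    sqrt_sd: np.ndarray     # fitted sqrt residual sd at the grid
    span: float


@dataclass(frozen=True)
class PrecisionWeights:
    weights: np.ndarray     # genes x samples, positive
    trend: Trend
    span: float


def _ols_fit(logcpm: np.ndarray, design: np.ndarray):
    """Vectorized gene-wise OLS: coefficients, fitted values, residual sd."""
    n, p = design.shape
    if n <= p:
        raise ValueError("need more samples than coefficients")
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank deficient")
    pinv = np.linalg.pinv(design)
    beta = logcpm @ pinv.T                      # G x p
    fitted = beta @ design.T                    # G x n
    resid = logcpm - fitted
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    return beta, fitted, np.sqrt(s2)


def voom_trend(logcpm: np.ndarray, design: np.ndarray, eff_lib_sizes: np.ndarray,
               span: float = 0.5) -> Trend:
    """Fit the sqrt-sd vs average log2-count trend by robust lowess."""
    logcpm = np.asarray(logcpm, float)
    if logcpm.shape[0] < 10:
        raise ValueError("too few genes (<10) to fit a stable mean-variance trend")
    _, fitted, sd = _ols_fit(logcpm, design)
    mean_log_lib = np.mean(np.log2(np.asarray(eff_lib_sizes, float) + 1.0))
    r = fitted.mean(axis=1) + mean_log_lib - np.log2(1e6)
    fit = lowess(np.sqrt(sd), r, frac=span, it=3, return_sorted=True)
    grid, vals = fit[:, 0], fit[:, 1]
    grid, idx = np.unique(grid, return_index=True)
    vals = np.maximum(vals[idx], 0.0)
    return Trend(grid=grid, sqrt_sd=vals, span=span)


def voom_weights(logcpm: np.ndarray, design: np.ndarray, eff_lib_sizes: np.ndarray,
                 trend: Trend) -> PrecisionWeights:
    """Per-observation precision weights from a fitted mean-variance trend.

    The trend is evaluated at each observation's fitted log2-count by linear
    interpolation with flat extrapolation beyond the grid ends; the weight is
    the predicted sqrt-sd to the power -4 (floored at ``SQRT_SD_FLOOR``).
    """
    logcpm = np.asarray(logcpm, float)
    _, fitted, _ = _ols_fit(logcpm, design)
    log_lib = np.log2(np.asarray(eff_lib_sizes, float) + 1.0)
    fitted_logcount = fitted + log_lib[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, trend.grid, trend.sqrt_sd)
    pred = np.maximum(pred, SQRT_SD_FLOOR)
    w = pred ** -4.0
    return PrecisionWeights(weights=w, trend=trend, span=trend.span)


def voom(logcpm: np.ndarray, design: np.ndarray, eff_lib_sizes: np.ndarray,
         span: float = 0.5) -> PrecisionWeights:
    """Convenience: trend fit followed by weight computation."""
    trend = voom_trend(logcpm, design, eff_lib_sizes, span)
    return voom_weights(logcpm, design, eff_lib_sizes, trend)
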