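"""Cross-sectional differential expression: gene-wise weighted linear models,
empirical-Bayes variance moderation, moderated t/F contrast tests, BH control.

Each gene's log2-cpm vector is fit by weighted least squares against a shared
design matrix with voom precision weights.  Residual variances are shrunk
toward a common prior by moment-matching the distribution of log s_g^2 against
a scaled log-F (closed-form digamma/trigamma matching), giving posterior
variances s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g) and d0 extra degrees of
freedom for the contrast tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger("dystromon")


@dataclass(frozen=True)
class LinearFit:
    coef: np.ndarray          # G x p
    cov_unscaled: np.ndarray  # G x p x p, (X'WX)^-1
    s2: np.ndarray            # G residual variances
    df_resid: float
    design: np.ndarray


@dataclass(frozen=True)
class ModeratedVariance:
    s2: np.ndarray
    df_resid: float
    prior_df: float           # d0, may be inf
    prior_s2: float           # s0^2
    posterior_s2: np.ndarray  # s~^2


def fit_weighted_lm(logcpm: np.ndarray, weights: np.ndarray, design: np.ndarray) -> LinearFit:
    """Gene-wise weighted least squares with a common design matrix."""
    y = np.asarray(logcpm, float)
    w = np.asarray(weights, float)
    X = np.asarray(design, float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name aliased columns: those whose removal does not lower the rank
        aliased = [j for j in range(p)
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design matrix is rank deficient (aliased columns: {aliased})")
    xtwx = np.einsum("gj,jp,jq->gpq", w, X, X)
    xtwy = np.einsum("gj,jp->gp", w * y, X)
    cov = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", cov, xtwy)
    resid = y - beta @ X.T
    s2 = np.einsum("gj,gj->g", w, resid ** 2) / (n - p)
    return LinearFit(coef=beta, cov_unscaled=cov, s2=s2, df_resid=float(n - p), design=X)


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex target)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def ebayes_moderate(s2: np.ndarray, df) -> ModeratedVariance:
    """Estimate the variance prior (d0, s0^2) and posterior variances.

    Moment matching on z = log s^2: under the scaled F model,
    E z = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2) and
    Var z = trigamma(d/2) + trigamma(d0/2).  When the observed spread of z does
    not exceed the chi-square component, d0 is infinite and all variances
    shrink to the common value.
    """
    s2 = np.asarray(s2, float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    if np.any(df <= 0):
        raise ValueError("all residual degrees of freedom must be positive")
    z = np.log(np.maximum(s2, 1e-300))
    if np.allclose(z, z[0], atol=1e-12):
        # degenerate: no sampling spread at all, shrink to the common value
        logger.info("ebayes_moderate: all variances identical; prior df infinite")
        return ModeratedVariance(s2=s2, df_resid=float(np.atleast_1d(df)[0]),
                                 prior_df=np.inf, prior_s2=float(s2[0]),
                                 posterior_s2=np.full_like(s2, s2[0]))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _inv_trigamma(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
        logger.info("ebayes_moderate: no excess variance heterogeneity; prior df infinite")
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return ModeratedVariance(s2=s2, df_resid=float(df[0]), prior_df=float(d0),
                             prior_s2=s0, posterior_s2=post)


def test_contrast(fit: LinearFit, mod: ModeratedVariance, contrast: np.ndarray,
                  gene_ids=None) -> pd.DataFrame:
    """Moderated t (1-df) or moderated F (multi-df) test of a contrast.

    ``contrast`` has one row per model coefficient; columns define the tested
    linear combinations.  Positive logFC means higher in the first-named group
    of the contrast (i.e. the sign of c'beta).
    """
    C = np.atleast_2d(np.asarray(contrast, float))
    if C.shape[0] != fit.coef.shape[1]:
        C = C.T
    if C.shape[0] != fit.coef.shape[1]:
        raise ValueError("contrast rows must match the number of coefficients")
    q = C.shape[1]
    G = fit.coef.shape[0]
    cb = fit.coef @ C                                   # G x q
    cvc = np.einsum("pk,gpq,ql->gkl", C, fit.cov_unscaled, C)  # G x q x q
    df_total = mod.df_resid + mod.prior_df
    s2 = mod.posterior_s2
    if q == 1:
        se = np.sqrt(cvc[:, 0, 0] * s2)
        tstat = cb[:, 0] / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        fstat = tstat ** 2
        logfc = cb[:, 0]
        stat = tstat
    else:
        sol = np.linalg.solve(cvc, cb)
        fstat = np.einsum("gq,gq->g", cb, sol) / (q * s2)
        if np.isinf(df_total):
            p = stats.chi2.sf(q * fstat, q)
        else:
            p = stats.f.sf(fstat, q, df_total)
        logfc = cb[:, 0]
        stat = fstat
    out = pd.DataFrame({
        "gene_id": list(gene_ids) if gene_ids is not None else np.arange(G),
        "logFC": logfc,
        "statistic": stat,
        "F": fstat,
        "p": p,
    })
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["mean_expr"] = (fit.coef @ fit.design.T).mean(axis=1)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagated, excluded
    from the effective number of tests); original order restored."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out
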