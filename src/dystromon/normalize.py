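"""Expression filtering and TMM between-sample normalization.

Lowly expressed genes are removed by a cpm rule (at least ``min_cpm`` counts
per million in at least ``ceil(min_frac * n_samples)`` samples, computed on raw
library sizes).  Between-sample scaling uses the trimmed mean of M-values:
for each sample a weighted mean of gene-wise log2 expression ratios against a
reference sample is taken after double-trimming extreme ratios (M) and extreme
abundances (A), and the resulting factors are rescaled to geometric mean one.
log2-cpm uses effective library sizes (library size x TMM factor) with
pseudo-counts 0.5 (numerator) and 1 (library).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import CountMatrix, ValidationError

logger = logging.getLogger("dystromon")


@dataclass(frozen=True)
class NormalizedExpression:
    """Filtered log2-cpm with per-sample TMM factors and effective library sizes."""

    gene_ids: tuple
    sample_ids: tuple
    tmm_factor: np.ndarray
    logcpm: np.ndarray
    eff_lib_sizes: np.ndarray


def cpm(cm: CountMatrix) -> np.ndarray:
    """Counts per million on raw library sizes (no pseudo-counts)."""
    return cm.counts / cm.lib_sizes * 1e6


def filter_by_cpm(cm: CountMatrix, min_cpm: float = 5.0, min_frac: float = 0.10) -> CountMatrix:
    """Keep genes with cpm >= min_cpm in at least ceil(min_frac * n) samples."""
    if min_cpm <= 0:
        raise ValueError("min_cpm must be positive")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    n = len(cm.sample_ids)
    need = math.ceil(min_frac * n)
    keep = (cpm(cm) >= min_cpm).sum(axis=1) >= need
    if not keep.any():
        raise ValidationError(
            f"cpm filter removed all {len(cm.gene_ids)} genes "
            f"(min_cpm={min_cpm}, required in >= {need}/{n} samples)"
        )
    out = cm.subset_genes(keep)
    logger.info(
        "filter_by_cpm: kept %d/%d genes (min_cpm=%g in >=%d/%d samples)",
        len(out.gene_ids), len(cm.gene_ids), min_cpm, need, n,
    )
    return out


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    """Single-sample TMM log2 factor against the reference column."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return None
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method weight: asymptotic variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    keep = np.ones(n, dtype=bool)
    for vals, frac in ((m, trim_m), (a, trim_a)):
        lo = math.floor(n * frac)
        hi = n - lo
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        keep &= (ranks >= lo) & (ranks < hi)
    if not keep.any():
        return None
    wk = w[keep]
    with np.errstate(divide="ignore"):
        inv = 1.0 / wk
    inv[~np.isfinite(inv)] = 0.0
    if inv.sum() == 0:
        return None
    return float(np.sum(inv * m[keep]) / inv.sum())


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean one.

    The reference sample is the one whose 75th-percentile cpm is closest to the
    mean of those percentiles across samples.  A sample sharing no expressed
    genes with the reference gets factor 1 with a warning.
    """
    if len(cm.sample_ids) < 2:
        raise ValueError("TMM needs at least two samples")
    libs = cm.lib_sizes.astype(float)
    if np.any(libs <= 0):
        raise ValueError("all library sizes must be positive")
    # all-zero genes carry no information and would perturb the reference
    # choice; drop them so padding with unexpressed genes is a no-op
    expressed = cm.counts.sum(axis=1) > 0
    counts = cm.counts[expressed]
    q75 = np.percentile(counts / libs, 75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.zeros(len(cm.sample_ids))
    for k in range(len(cm.sample_ids)):
        if k == ref:
            continue
        f = _tmm_pair(counts[:, k], counts[:, ref], libs[k], libs[ref], trim_m, trim_a)
        if f is None:
            logger.warning("tmm_factors: sample %r shares no usable genes with reference; factor set to 1",
                           cm.sample_ids[k])
            f = 0.0
        log_factors[k] = f
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(cm: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """log2((count + 0.5) / (effective library size + 1) * 1e6)."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("TMM factors must be positive")
    eff = cm.lib_sizes * factors
    return np.log2((cm.counts + 0.5) / (eff + 1.0) * 1e6)


def normalize(cm: CountMatrix, min_cpm: float = 5.0, min_frac: float = 0.10,
              trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizedExpression:
    """Filter, compute TMM factors, and return log2-cpm in one step."""
    filtered = filter_by_cpm(cm, min_cpm, min_frac)
    factors = tmm_factors(filtered, trim_m, trim_a)
    return NormalizedExpression(
        gene_ids=filtered.gene_ids,
        sample_ids=filtered.sample_ids,
        tmm_factor=factors,
        logcpm=log_cpm(filtered, factors),
        eff_lib_sizes=filtered.lib_sizes * factors,
    )
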