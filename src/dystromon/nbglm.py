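"""Negative-binomial GLM engine with quasi-likelihood F-tests.

Counts are modeled as NB(mean mu, dispersion phi) with Var = mu + phi mu^2 and
log mu = offset + X beta (offsets are log effective library sizes; reported
logFCs are on the log2 scale).  Gene-wise dispersions are estimated by
maximizing the Cox-Reid adjusted profile likelihood on a log-spaced grid with
deterministic ternary refinement, then smoothed by a locally weighted trend on
log mean cpm.  Gene-wise quasi-dispersions (deviance / residual df at the
trended dispersion) are squeezed toward the trend by empirical-Bayes F moment
matching, and contrasts are tested with the quasi-likelihood F statistic
F = (deviance drop / q) / s^2, referred to F(q, prior df + residual df).

The same engine drives the treatment-response concordance report and the
human-cohort covariate tests (omnibus / group / steroid, and covariate-block
principal-component association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import CountMatrix
from .de_linear import bh_adjust, ebayes_moderate
from .normalize import filter_by_cpm, tmm_factors

logger = logging.getLogger("dystromon")

LN2 = np.log(2.0)
_PHI_GRID = np.logspace(np.log10(1e-4), np.log10(4.0), 41)
_MIN_PHI = 1e-6


@dataclass
class NBFit:
    gene_ids: tuple
    counts: np.ndarray
    design: np.ndarray
    offsets: np.ndarray
    coef: np.ndarray                 # natural-log scale, G x p
    mu: np.ndarray                   # fitted means, G x n
    dispersion: np.ndarray           # gene-wise Cox-Reid estimates
    trended_dispersion: np.ndarray
    deviance: np.ndarray
    df_resid: float
    quasi_s2: np.ndarray             # raw deviance / df
    squeezed_s2: np.ndarray
    prior_df: float
    converged: np.ndarray
    colnames: tuple = ()

    @property
    def log2fc(self) -> np.ndarray:
        return self.coef / LN2


def _nb_loglik(y, mu, phi):
    """Per-gene NB log-likelihood (phi may be per-gene; Poisson limit below
    the dispersion floor)."""
    phi = np.asarray(phi, float).reshape(-1, 1)
    phi_s = np.maximum(phi, _MIN_PHI)
    r = 1.0 / phi_s
    nb = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
          + y * np.log(phi_s * mu / (1.0 + phi_s * mu))
          - r * np.log1p(phi_s * mu))
    pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    return np.where(phi < _MIN_PHI, pois, nb).sum(axis=1)


def nb_deviance(y, mu, phi):
    """NB residual deviance per gene: 2 * (loglik(saturated) - loglik(mu));
    reduces to the Poisson deviance below the dispersion floor."""
    phi = np.asarray(phi, float).reshape(-1, 1)
    phi_s = np.maximum(phi, _MIN_PHI)
    r = 1.0 / phi_s
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + r) * np.log((1.0 + phi_s * y) / (1.0 + phi_s * mu))
    unit = np.where(phi < _MIN_PHI, term1 - (y - mu), term1 - term2)
    return 2.0 * unit.sum(axis=1)


def _irls(counts, X, offsets, phi, beta0=None, max_iter=50, tol=1e-10):
    """Vectorized IRLS for NB GLMs with log link and offsets.

    phi may be a scalar or a per-gene vector.  Returns (beta, mu, deviance,
    converged, xtwx).
    """
    y = np.asarray(counts, float)
    G, n = y.shape
    p = X.shape[1]
    phi_col = np.broadcast_to(np.asarray(phi, float).reshape(-1, 1), (G, 1))
    if beta0 is None:
        # start from the log of a lightly shrunk mean cpm in each column space
        init = np.log((y + 0.5) / np.exp(offsets)[None, :])
        beta = init @ np.linalg.pinv(X).T
    else:
        beta = beta0.copy()
    eta = beta @ X.T + offsets[None, :]
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, phi_col)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + phi_col * mu)                    # working weights
        z = (eta - offsets[None, :]) + (y - mu) / mu
        xtwx = np.einsum("gj,jp,jq->gpq", w[active], X, X)
        xtwz = np.einsum("gj,jp->gp", (w * z)[active], X)
        # tiny ridge keeps boundary genes (all-zero groups) finite
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        beta[active] = new_beta
        eta = np.clip(beta @ X.T + offsets[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = nb_deviance(y, mu, phi_col)
        delta = np.abs(new_dev - dev) / (np.abs(new_dev) + 1.0)
        converged |= delta < tol
        dev = new_dev
    w = mu / (1.0 + phi_col * mu)
    xtwx = np.einsum("gj,jp,jq->gpq", w, X, X)
    return beta, mu, dev, converged, xtwx


def _cr_apl(counts, X, offsets, phi, beta0=None):
    """Cox-Reid adjusted profile log-likelihood at per-gene dispersion phi."""
    beta, mu, _, _, xtwx = _irls(counts, X, offsets, phi, beta0=beta0, max_iter=30)
    ll = _nb_loglik(np.asarray(counts, float), mu, phi)
    sign, logdet = np.linalg.slogdet(xtwx + 1e-12 * np.eye(X.shape[1])[None])
    return ll - 0.5 * logdet, beta


def estimate_dispersion(counts, X, offsets, span: float = 0.3):
    """Gene-wise Cox-Reid dispersions (grid + ternary refinement) and a
    locally weighted trend on log mean cpm."""
    y = np.asarray(counts, float)
    G = y.shape[0]
    apls = np.empty((len(_PHI_GRID), G))
    beta0 = None
    for i, phi in enumerate(_PHI_GRID):
        apls[i], beta0 = _cr_apl(y, X, offsets, np.full(G, phi), beta0=beta0)
    best = np.argmax(apls, axis=0)
    lo = np.log(_PHI_GRID[np.maximum(best - 1, 0)])
    hi = np.log(_PHI_GRID[np.minimum(best + 1, len(_PHI_GRID) - 1)])
    for _ in range(25):
        third = (hi - lo) / 3.0
        x1, x2 = lo + third, hi - third
        f1, _ = _cr_apl(y, X, offsets, np.exp(x1), beta0=beta0)
        f2, _ = _cr_apl(y, X, offsets, np.exp(x2), beta0=beta0)
        lo = np.where(f1 < f2, x1, lo)
        hi = np.where(f1 < f2, hi, x2)
    phi_hat = np.exp(0.5 * (lo + hi))
    mean_cpm = (y / np.exp(offsets)[None, :] * 1e6).mean(axis=1)
    logx = np.log(np.maximum(mean_cpm, 1e-8))
    if G >= 10:
        fit = lowess(np.log(phi_hat), logx, frac=span, it=3, return_sorted=True)
        gx, gy = np.unique(fit[:, 0], return_index=True)
        trended = np.exp(np.interp(logx, gx, fit[gy, 1]))
    else:
        trended = np.full(G, np.exp(np.median(np.log(phi_hat))))
    return phi_hat, np.maximum(trended, _MIN_PHI)


def fit_nb_glm(counts, design, offsets, gene_ids=None, colnames=(),
               dispersion_span: float = 0.3) -> NBFit:
    """Full NB GLM pipeline: CR dispersions, trend, fit at trended dispersion,
    quasi-dispersions squeezed by empirical-Bayes F moment matching."""
    y = np.asarray(counts, float)
    X = np.asarray(design, float)
    offsets = np.asarray(offsets, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        aliased = [j for j in range(p)
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)]
        raise ValueError(f"design matrix is rank deficient (aliased columns: {aliased})")
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    G = y.shape[0]
    gene_ids = tuple(gene_ids) if gene_ids is not None else tuple(range(G))
    phi_hat, trended = estimate_dispersion(y, X, offsets, span=dispersion_span)
    beta, mu, dev, converged, _ = _irls(y, X, offsets, trended)
    if not converged.all():
        logger.warning("fit_nb_glm: %d genes did not converge; flagged", int((~converged).sum()))
    df_resid = float(n - p)
    s2 = np.maximum(dev, 0.0) / df_resid
    if G >= 10:
        mod = ebayes_moderate(np.maximum(s2, 1e-10), df_resid)
        squeezed, prior_df = mod.posterior_s2, mod.prior_df
    else:
        squeezed, prior_df = s2, 0.0
    return NBFit(gene_ids=gene_ids, counts=y, design=X, offsets=offsets, coef=beta, mu=mu,
                 dispersion=phi_hat, trended_dispersion=trended, deviance=dev,
                 df_resid=df_resid, quasi_s2=s2, squeezed_s2=squeezed,
                 prior_df=prior_df, converged=converged, colnames=tuple(colnames))


def qlf_test(fit: NBFit, coef_idx, subset=None) -> pd.DataFrame:
    """Quasi-likelihood F-test that the coefficients in ``coef_idx`` are zero.

    The null model (design without those columns) is refit at the same trended
    dispersion; F = (deviance drop / q) / squeezed s^2 on F(q, prior + resid df).
    With infinite prior df the statistic reduces to a scaled chi-square test.
    Non-converged genes get NaN p-values and are excluded from the BH pool.
    """
    y = np.asarray(fit.counts, float)
    coef_idx = np.atleast_1d(np.asarray(coef_idx, int))
    q = coef_idx.size
    X0 = np.delete(fit.design, coef_idx, axis=1)
    if subset is not None:
        sel = np.asarray(subset)
        if sel.dtype != bool:
            pos = {g: i for i, g in enumerate(fit.gene_ids)}
            sel = np.isin(np.arange(len(fit.gene_ids)), [pos[g] for g in subset])
    else:
        sel = np.ones(len(fit.gene_ids), dtype=bool)
    idx = np.flatnonzero(sel)
    _, _, dev0, conv0, _ = _irls(y[idx], X0, fit.offsets, fit.trended_dispersion[idx])
    drop = np.maximum(dev0 - fit.deviance[idx], 0.0)
    s2 = fit.squeezed_s2[idx]
    F = (drop / q) / np.maximum(s2, 1e-300)
    df2 = fit.prior_df + fit.df_resid
    ok = fit.converged[idx] & conv0
    if np.isinf(df2):
        p = stats.chi2.sf(q * F, q)
    else:
        p = stats.f.sf(F, q, df2)
    p = np.where(ok, p, np.nan)
    lfc = fit.log2fc[idx][:, coef_idx[0]] if q == 1 else fit.log2fc[idx][:, coef_idx].mean(axis=1)
    out = pd.DataFrame({
        "gene_id": [fit.gene_ids[i] for i in idx],
        "logFC": lfc,
        "F": F,
        "p": p,
    })
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class ConcordanceReport:
    analyzed_genes: list
    n_requested: int
    n_dropped_by_filter: int
    desired_effect: pd.Series          # d_g = -disease logFC
    arm_logfc: pd.DataFrame            # per-arm estimated log2FC vs reference
    concordant: pd.Series              # bool per analyzed gene
    n_concordant: int
    omnibus: pd.DataFrame
    pairwise: dict = field(default_factory=dict)


def treatment_concordance(arm_logfc: pd.DataFrame, disease_logfc: pd.Series,
                          arms=("PMO", "PS49")):
    """Concordance flags: both arms' logFC signs equal the desired-effect sign
    (desired effect = the negative of the disease logFC)."""
    missing = [g for g in arm_logfc.index if g not in disease_logfc.index]
    if missing:
        logger.warning("treatment_concordance: %d genes lack a disease logFC; excluded",
                       len(missing))
        arm_logfc = arm_logfc.drop(index=missing)
    d = -disease_logfc.loc[arm_logfc.index]
    sign_d = np.sign(d)
    conc = pd.Series(True, index=arm_logfc.index)
    for arm in arms:
        conc &= np.sign(arm_logfc[arm]) == sign_d
    conc &= sign_d != 0
    return conc, d


def treatment_analysis(cm: CountMatrix, meta: pd.DataFrame, gene_list,
                       disease_logfc: pd.Series, min_cpm: float = 5.0,
                       min_frac: float = 0.10, ref_arm: str = "saline",
                       arms=("PMO", "PS49"), fdr: float = 0.05) -> ConcordanceReport:
    """MoTreat-style analysis: NB GLM across three arms on a pre-specified
    disease gene list, QLF omnibus then pairwise tests, concordance scoring.

    Genes from the list failing the expression filter are dropped and counted
    (the report states both numbers).
    """
    filtered = filter_by_cpm(cm, min_cpm, min_frac)
    keep = [g for g in gene_list if g in set(filtered.gene_ids)]
    n_dropped = len(list(gene_list)) - len(keep)
    sub = filtered.subset_genes(keep)
    factors = tmm_factors(filtered)  # factors from the full filtered matrix
    offsets = np.log(filtered.lib_sizes * factors)
    arm_vals = meta.set_index("sample_id").loc[list(cm.sample_ids), "treatment"].to_numpy()
    levels = [ref_arm] + [a for a in arms]
    cols = [np.ones(len(arm_vals))] + [(arm_vals == a).astype(float) for a in arms]
    X = np.column_stack(cols)
    fit = fit_nb_glm(sub.counts, X, offsets, gene_ids=sub.gene_ids,
                     colnames=tuple(["intercept"] + [f"arm[{a}]" for a in arms]))
    omnibus = qlf_test(fit, [1, 2])
    pairwise = {arm: qlf_test(fit, [i + 1])
                for i, arm in enumerate(arms)}
    arm_lfc = pd.DataFrame({arm: pairwise[arm].set_index("gene_id")["logFC"]
                            for arm in arms})
    conc, d = treatment_concordance(arm_lfc, disease_logfc, arms)
    logger.info("treatment_analysis: %d genes requested, %d dropped by filter, "
                "%d analyzed, %d concordant", len(list(gene_list)), n_dropped,
                len(keep), int(conc.sum()))
    return ConcordanceReport(
        analyzed_genes=list(arm_lfc.index), n_requested=len(list(gene_list)),
        n_dropped_by_filter=n_dropped, desired_effect=d, arm_logfc=arm_lfc,
        concordant=conc, n_concordant=int(conc.sum()), omnibus=omnibus,
        pairwise=pairwise,
    )


def build_cohort_design(meta: pd.DataFrame, group_col="group", age_col="age",
                        steroid_col="treatment", case_level="DMD"):
    """Design: intercept, group, centered age, age x group, steroid.

    Healthy subjects are coded steroid = 0 by definition, so the group
    coefficient reads "untreated case vs healthy at mean age"."""
    group = (meta[group_col].astype(str) == case_level).astype(float).to_numpy()
    age = meta[age_col].astype(float).to_numpy()
    age_c = age - age.mean()
    steroid = meta[steroid_col].fillna(0).astype(float).to_numpy()
    steroid = np.where(group == 0, 0.0, steroid)
    X = np.column_stack([np.ones(len(meta)), group, age_c, age_c * group, steroid])
    names = ("intercept", "group", "age", "age:group", "steroid")
    return X, names


def cohort_tests(cm: CountMatrix, meta: pd.DataFrame, fdr: float = 0.05,
                 min_cpm: float = 5.0, min_frac: float = 0.10,
                 include_interaction: bool = True):
    """Omnibus / group / treatment QLF tests for the human cohort.

    Omnibus tests {group, age x group, steroid} jointly (3 df); within
    omnibus-significant genes, the group test covers {group, age x group}
    (2 df) and the treatment test {steroid} (1 df).  The returned group table
    carries the baseline-age group log2FC and the age x group interaction
    coefficient per gene.
    """
    filtered = filter_by_cpm(cm, min_cpm, min_frac)
    factors = tmm_factors(filtered)
    offsets = np.log(filtered.lib_sizes * factors)
    meta = meta.set_index("sample_id").loc[list(filtered.sample_ids)].reset_index()
    X, names = build_cohort_design(meta)
    if not include_interaction:
        X = X[:, [0, 1, 2, 4]]
        names = ("intercept", "group", "age", "steroid")
    fit = fit_nb_glm(filtered.counts, X, offsets, gene_ids=filtered.gene_ids,
                     colnames=names)
    omni_idx = [names.index("group")] + \
        ([names.index("age:group")] if include_interaction else []) + [names.index("steroid")]
    omnibus = qlf_test(fit, omni_idx)
    sig = omnibus.loc[omnibus["adj_p"] < fdr, "gene_id"].tolist()
    group_idx = [names.index("group")] + \
        ([names.index("age:group")] if include_interaction else [])
    group_tab = qlf_test(fit, group_idx, subset=sig)
    treat_tab = qlf_test(fit, [names.index("steroid")], subset=sig)
    pos = {g: i for i, g in enumerate(fit.gene_ids)}
    gsel = [pos[g] for g in group_tab["gene_id"]]
    group_tab = group_tab.assign(
        baseline_log2fc=fit.log2fc[gsel, names.index("group")],
        interaction=(fit.log2fc[gsel, names.index("age:group")]
                     if include_interaction else np.nan),
        steroid_log2fc=fit.log2fc[gsel, names.index("steroid")],
    )
    return {"fit": fit, "omnibus": omnibus, "group": group_tab, "treatment": treat_tab}


def block_pc_summary(block: pd.DataFrame, anchor: str | None = None):
    """First principal component of a standardized covariate block.

    Subjects with missing values are excluded (logged).  Orientation is fixed
    so the loading on the anchor variable (default: first column) is positive.
    Returns (scores indexed by subject, variance-explained fraction, loadings).
    """
    complete = block.dropna()
    if len(complete) < len(block):
        logger.info("block_pc_summary: excluded %d subjects with missing values",
                    len(block) - len(complete))
    if len(complete) < 3:
        raise ValueError("need at least 3 complete subjects for PCA")
    vals = complete.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant covariates in block: "
                         f"{list(complete.columns[sd == 0])}")
    z = (vals - vals.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = pd.Series(vt[0], index=complete.columns)
    scores = pd.Series(z @ vt[0], index=complete.index)
    anchor = anchor if anchor is not None else complete.columns[0]
    if loadings[anchor] < 0:
        loadings, scores = -loadings, -scores
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return scores, var_explained, loadings


def pc_association(cm: CountMatrix, pc_scores: pd.Series,
                   min_cpm: float = 5.0, min_frac: float = 0.10) -> pd.DataFrame:
    """QLF test of each gene against a covariate-block PC (sole covariate)."""
    sids = [s for s in cm.sample_ids if s in pc_scores.index]
    sub = cm.subset_samples(sids)
    filtered = filter_by_cpm(sub, min_cpm, min_frac)
    factors = tmm_factors(filtered)
    offsets = np.log(filtered.lib_sizes * factors)
    pc = pc_scores.loc[list(filtered.sample_ids)].to_numpy(dtype=float)
    if pc.std() == 0:
        raise ValueError("PC scores are constant (collinear with the intercept)")
    X = np.column_stack([np.ones(pc.size), pc])
    fit = fit_nb_glm(filtered.counts, X, offsets, gene_ids=filtered.gene_ids,
                     colnames=("intercept", "pc1"))
    return qlf_test(fit, [1])
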