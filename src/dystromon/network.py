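"""Weighted co-expression network construction and module detection per tissue.

The adjacency between genes i and j is |Pearson cor|^beta with the soft power
beta chosen as the smallest candidate achieving an approximately scale-free
degree distribution (R^2 of log-frequency vs log-connectivity above a target).
The topological overlap matrix (TOM) turns adjacency into a similarity that
rewards shared neighbors; modules are branches of an average-linkage tree on
1 - TOM, cut at a fixed height, with small clusters left unassigned ("grey")
and modules with highly correlated eigengenes merged.  Each module is
summarized by its eigengene (first principal component of the z-scored
member expression) and each gene by its kME (correlation with the eigengene
of its own module).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("dystromon")

#: Module label sequence (cosmetic; module identity is membership).
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
)
GREY = "grey"


@dataclass(frozen=True)
class CoexpressionNetwork:
    gene_ids: tuple
    soft_power: int
    adjacency: np.ndarray
    tom: np.ndarray
    tissue: str = ""
    scale_free_r2: float = np.nan


@dataclass
class ModulePartition:
    gene_ids: tuple
    labels: tuple                      # per-gene module label, GREY = unassigned
    eigengenes: dict = field(default_factory=dict)   # label -> per-sample vector
    var_explained: dict = field(default_factory=dict)
    kme: dict = field(default_factory=dict)          # gene -> kME in its module

    def members(self, label):
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    @property
    def module_labels(self):
        seen = []
        for l in self.labels:
            if l != GREY and l not in seen:
                seen.append(l)
        return seen


def _drop_constant(expr: np.ndarray, gene_ids):
    sd = expr.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        logger.warning("network: excluding %d constant-expression genes: %s",
                       len(dropped), dropped[:10])
    return expr[keep], [g for g, k in zip(gene_ids, keep) if k]


def adjacency_matrix(expr: np.ndarray, power: int, signed: bool = False) -> np.ndarray:
    """|cor|^power (unsigned) or ((1+cor)/2)^power (signed) adjacency."""
    r = np.corrcoef(expr)
    a = ((1.0 + r) / 2.0) ** power if signed else np.abs(r) ** power
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, 1.0)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of connectivity-bin frequency on mean
    connectivity (the scale-free topology fit index)."""
    k = adjacency.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return 0.0
    which = np.clip(np.digitize(k, edges[1:-1]), 0, edges.size - 2)
    freq = np.bincount(which, minlength=edges.size - 1).astype(float)
    kmean = np.array([k[which == b].mean() if freq[b] else np.nan
                      for b in range(edges.size - 1)])
    ok = (freq > 0) & (kmean > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(kmean[ok])
    y = np.log10(freq[ok] / freq[ok].sum())
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2) if np.isfinite(r) else 0.0


def pick_soft_power(expr: np.ndarray, candidates=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
                    target_r2: float = 0.8, signed: bool = False):
    """Smallest candidate power reaching the scale-free target; fallback 6."""
    expr = np.asarray(expr, float)
    if expr.shape[0] < 50:
        raise ValueError("need at least 50 genes to assess scale-free topology")
    expr, _ = _drop_constant(expr, list(range(expr.shape[0])))
    r = np.abs(np.corrcoef(expr))
    best_r2 = {}
    for power in candidates:
        a = ((1.0 + r) / 2.0) ** power if signed else r ** power
        np.fill_diagonal(a, 1.0)
        r2 = scale_free_fit(a)
        best_r2[power] = r2
        if r2 >= target_r2:
            return int(power), r2
    if len(candidates) == 1:
        power = candidates[0]
        logger.warning("pick_soft_power: single candidate %d below target (R2=%.2f)",
                       power, best_r2[power])
        return int(power), best_r2[power]
    logger.warning("pick_soft_power: no candidate reached R2>=%.2f; falling back to 6",
                   target_r2)
    return 6, best_r2.get(6, scale_free_fit(r ** 6))


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij the shared-neighbor sum and k the connectivity (diagonal excluded)."""
    a = np.asarray(adjacency, float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0) - np.diag(a)
    l = a @ a - a * (np.diag(a)[:, None] + np.diag(a)[None, :])
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def check_network_filter(cm, min_cpm: float = 10.0, min_frac: float = 0.40,
                         override: bool = False) -> None:
    """Refuse count matrices not pre-filtered at the stricter network threshold.

    Network estimation assumes every gene clears >= ``min_cpm`` cpm in at least
    ``ceil(min_frac * n)`` samples; matrices filtered only at the looser DE
    threshold are rejected unless ``override`` is set.
    """
    import math
    n = len(cm.sample_ids)
    need = math.ceil(min_frac * n)
    cpm = cm.counts / cm.lib_sizes * 1e6
    bad = int((np.sum(cpm >= min_cpm, axis=1) < need).sum())
    if bad:
        msg = (f"{bad} genes fail the network expression filter "
               f"(>= {min_cpm} cpm in >= {need}/{n} samples)")
        if not override:
            raise ValueError(msg + "; filter at the network threshold first "
                             "or pass override=True")
        logger.warning("check_network_filter overridden: %s", msg)


def build_network(expr: np.ndarray, gene_ids, tissue: str = "",
                  candidates=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
                  target_r2: float = 0.8, signed: bool = False) -> CoexpressionNetwork:
    expr = np.asarray(expr, float)
    expr, gene_ids = _drop_constant(expr, list(gene_ids))
    power, r2 = pick_soft_power(expr, candidates, target_r2, signed)
    a = adjacency_matrix(expr, power, signed)
    return CoexpressionNetwork(gene_ids=tuple(gene_ids), soft_power=power,
                               adjacency=a, tom=tom_similarity(a), tissue=tissue,
                               scale_free_r2=r2)


def module_eigengene(expr: np.ndarray):
    """First principal component of the z-scored module expression.

    Returns (eigengene per sample, variance-explained fraction).  Orientation:
    the mean correlation of member genes with the eigengene is non-negative.
    Zero-variance genes are dropped from the computation.
    """
    expr = np.asarray(expr, float)
    if expr.ndim != 2 or expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("module eigengene needs >=2 genes and >=3 samples")
    sd = expr.std(axis=1)
    if np.any(sd == 0):
        logger.warning("module_eigengene: dropping %d zero-variance genes", int((sd == 0).sum()))
        expr = expr[sd > 0]
        sd = sd[sd > 0]
    z = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    corr = (z @ eig) / (np.linalg.norm(z, axis=1) * np.linalg.norm(eig))
    if corr.mean() < 0:
        eig = -eig
    return eig, var_explained


def detect_modules(tom: np.ndarray, expr: np.ndarray, gene_ids,
                   min_size: int = 30, cut_height: float = 0.95,
                   merge_cutoff: float = 0.75) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a static branch cut.

    Clusters below ``min_size`` become grey; modules whose eigengenes correlate
    above ``merge_cutoff`` are merged iteratively (most correlated pair first);
    labels are colors assigned by decreasing module size.
    """
    tom = np.asarray(tom, float)
    expr = np.asarray(expr, float)
    gene_ids = list(gene_ids)
    n = tom.shape[0]
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    assign = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters = {}
    for idx, c in enumerate(assign):
        clusters.setdefault(c, []).append(idx)
    groups = [g for g in clusters.values() if len(g) >= min_size]
    if not groups:
        logger.warning("detect_modules: no cluster reached min size %d; all genes grey", min_size)
        return ModulePartition(gene_ids=tuple(gene_ids), labels=(GREY,) * n)
    # iterative eigengene merge
    while len(groups) > 1:
        eigs = [module_eigengene(expr[g])[0] for g in groups]
        m = len(groups)
        best, best_r = None, merge_cutoff
        for i in range(m):
            for j in range(i + 1, m):
                r = abs(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if r >= best_r:
                    best, best_r = (i, j), r
        if best is None:
            break
        i, j = best
        groups[i] = sorted(groups[i] + groups[j])
        del groups[j]
    groups.sort(key=lambda g: (-len(g), g[0]))
    labels = [GREY] * n
    part = ModulePartition(gene_ids=tuple(gene_ids), labels=())
    for color, g in zip(COLOR_SEQUENCE, groups):
        for idx in g:
            labels[idx] = color
    if len(groups) > len(COLOR_SEQUENCE):
        for extra, g in enumerate(groups[len(COLOR_SEQUENCE):]):
            for idx in g:
                labels[idx] = f"module{len(COLOR_SEQUENCE) + extra + 1}"
    part.labels = tuple(labels)
    for label in part.module_labels:
        idx = [i for i, l in enumerate(labels) if l == label]
        eig, ve = module_eigengene(expr[idx])
        part.eigengenes[label] = eig
        part.var_explained[label] = ve
    # per-gene kME against the gene's own module eigengene
    for i, (g, l) in enumerate(zip(gene_ids, labels)):
        if l == GREY:
            continue
        x = expr[i]
        if x.std() == 0:
            continue
        part.kme[g] = float(np.corrcoef(x, part.eigengenes[l])[0, 1])
    logger.info("detect_modules: %d modules (sizes %s), %d grey genes",
                len(groups), [len(g) for g in groups], labels.count(GREY))
    return part


def kme_hubs(expr: np.ndarray, partition: ModulePartition, top_k: int = 5,
             kme_threshold: float | None = None) -> dict:
    """Per-module hub genes: top-k by kME, or all above a kME threshold."""
    hubs = {}
    for label in partition.module_labels:
        members = [(g, partition.kme.get(g, -np.inf)) for g in partition.members(label)]
        members = [(g, k) for g, k in members if np.isfinite(k)]
        members.sort(key=lambda t: (-t[1], t[0]))
        if kme_threshold is not None:
            hubs[label] = [g for g, k in members if k >= kme_threshold]
        else:
            hubs[label] = [g for g, _ in members[:top_k]]
    return hubs
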