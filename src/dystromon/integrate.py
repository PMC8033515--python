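"""Cross-tissue integration of module partitions and co-expression networks.

Four views of how the blood and muscle signatures relate:
membership overlap of module pairs (Jaccard index and overlap coefficient,
computed on the intersection of gene universes with unassigned genes
excluded); community-structure validation (the fraction of within-module
edges of one tissue's modules that are also edges in the other tissue's
network, after binarizing both networks at the same edge-density quantile);
Pearson cross-correlation of module eigengenes over matched samples; and a
"remote sensor" scan correlating single hub genes in blood with whole-module
eigengenes in muscle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de_linear import bh_adjust
from .network import GREY, CoexpressionNetwork, ModulePartition

logger = logging.getLogger("dystromon")


@dataclass
class IntegrationReport:
    module_overlap: pd.DataFrame
    csv_blood_in_muscle: float
    csv_muscle_in_blood: float
    csv_per_module: pd.DataFrame
    eigengene_correlation: pd.DataFrame
    hub_sensors: pd.DataFrame


def _module_sets(partition: ModulePartition, universe):
    uni = set(universe)
    out = {}
    for label in partition.module_labels:
        s = {g for g in partition.members(label) if g in uni}
        out[label] = s
    return out


def module_overlap(partition_a: ModulePartition, partition_b: ModulePartition) -> pd.DataFrame:
    """Jaccard and overlap coefficient for every module pair on the shared
    gene universe (grey excluded)."""
    universe = set(partition_a.gene_ids) & set(partition_b.gene_ids)
    mods_a = _module_sets(partition_a, universe)
    mods_b = _module_sets(partition_b, universe)
    rows = []
    for la, sa in mods_a.items():
        for lb, sb in mods_b.items():
            if not sa or not sb:
                rows.append((la, lb, 0, 0.0, 0.0, True))
                continue
            inter = len(sa & sb)
            jacc = inter / len(sa | sb)
            ovl = inter / min(len(sa), len(sb))
            rows.append((la, lb, inter, jacc, ovl, False))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "shared_genes",
                                       "jaccard", "overlap_coef", "empty_flag"])


def _binarize(net: CoexpressionNetwork, genes, quantile: float) -> np.ndarray:
    pos = {g: i for i, g in enumerate(net.gene_ids)}
    idx = np.array([pos[g] for g in genes])
    a = net.adjacency[np.ix_(idx, idx)]
    iu = np.triu_indices(len(genes), k=1)
    vals = a[iu]
    thresh = np.quantile(vals, 1.0 - quantile)
    edges = np.zeros_like(a, dtype=bool)
    # strictly positive adjacency required: a degenerate all-equal (e.g. empty)
    # matrix must yield no edges, not all of them
    edges[iu] = (vals >= thresh) & (vals > 0)
    return edges | edges.T


def csv_index(modules_from: ModulePartition, native_net: CoexpressionNetwork,
              foreign_net: CoexpressionNetwork, edge_quantile: float = 0.05):
    """Relative community-structure validation index, in percent.

    100 x (within-module native edges preserved in the foreign network) /
    (within-module native edges), over the shared gene universe, with a
    per-module breakdown.  Undefined (NA) when a module has no native edges.
    """
    genes = [g for g in native_net.gene_ids
             if g in set(foreign_net.gene_ids) and g in set(modules_from.gene_ids)]
    if len(genes) < 2:
        raise ValueError("no shared genes between the two networks")
    native = _binarize(native_net, genes, edge_quantile)
    foreign = _binarize(foreign_net, genes, edge_quantile)
    label_of = dict(zip(modules_from.gene_ids, modules_from.labels))
    labels = np.array([label_of[g] for g in genes])
    rows = []
    tot_native = tot_both = 0
    for mod in modules_from.module_labels:
        idx = np.flatnonzero(labels == mod)
        if idx.size < 2:
            rows.append((mod, 0, 0, np.nan))
            continue
        sub_native = native[np.ix_(idx, idx)]
        sub_foreign = foreign[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        n_native = int(sub_native[iu].sum())
        n_both = int((sub_native[iu] & sub_foreign[iu]).sum())
        tot_native += n_native
        tot_both += n_both
        frac = 100.0 * n_both / n_native if n_native else np.nan
        if n_native == 0:
            logger.warning("csv_index: module %r has no within-module native edges", mod)
        rows.append((mod, n_native, n_both, frac))
    per_module = pd.DataFrame(rows, columns=["module", "native_edges",
                                             "preserved_edges", "csv_pct"])
    overall = 100.0 * tot_both / tot_native if tot_native else np.nan
    return overall, per_module


def _pearson_p(r: float, n: int) -> float:
    if n < 3 or not np.isfinite(r):
        return np.nan
    r = np.clip(r, -1.0, 1.0)
    if abs(r) >= 1.0 - 1e-12:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(stats.t.sf(abs(t), n - 2))


def eigengene_cross_correlation(me_a: dict, me_b: dict, matched_idx_a, matched_idx_b,
                                display_threshold: float = 0.5) -> pd.DataFrame:
    """Pearson correlation of each pair of module eigengenes over matched samples,
    with t-transform p-values, BH across all pairs, and a display flag for
    |r| above the threshold."""
    ia = np.asarray(matched_idx_a)
    ib = np.asarray(matched_idx_b)
    if ia.size != ib.size or ia.size < 3:
        raise ValueError("need at least 3 matched samples")
    rows = []
    for la, ea in me_a.items():
        for lb, eb in me_b.items():
            r = float(np.corrcoef(ea[ia], eb[ib])[0, 1])
            rows.append((la, lb, r, _pearson_p(r, ia.size)))
    tab = pd.DataFrame(rows, columns=["module_a", "module_b", "r", "p"])
    tab["adj_p"] = bh_adjust(tab["p"].to_numpy())
    tab["displayed"] = tab["r"].abs() > display_threshold
    return tab


def hub_sensor_scan(blood_expr: np.ndarray, blood_genes, hubs: dict,
                    muscle_eigengenes: dict, matched_idx_blood, matched_idx_muscle) -> pd.DataFrame:
    """Correlate each blood hub gene with each muscle module eigengene.

    Rows sorted by BH-adjusted p; a significant row means a single blood gene
    tracks a whole co-expressed muscle module ("remote sensor")."""
    ib = np.asarray(matched_idx_blood)
    im = np.asarray(matched_idx_muscle)
    pos = {g: i for i, g in enumerate(blood_genes)}
    rows = []
    for blood_mod, genes in hubs.items():
        for g in genes:
            x = blood_expr[pos[g]][ib]
            if x.std() == 0:
                logger.warning("hub_sensor_scan: hub %r has zero variance; skipped", g)
                continue
            for mmod, eig in muscle_eigengenes.items():
                r = float(np.corrcoef(x, eig[im])[0, 1])
                rows.append((g, blood_mod, mmod, r, _pearson_p(r, ib.size)))
    tab = pd.DataFrame(rows, columns=["hub_gene", "blood_module", "muscle_module", "r", "p"])
    tab["adj_p"] = bh_adjust(tab["p"].to_numpy()) if len(tab) else []
    return tab.sort_values(["adj_p", "hub_gene"], kind="mergesort").reset_index(drop=True)


def integrate(partition_blood: ModulePartition, partition_muscle: ModulePartition,
              net_blood: CoexpressionNetwork, net_muscle: CoexpressionNetwork,
              blood_expr: np.ndarray, hubs: dict,
              matched_idx_blood, matched_idx_muscle,
              edge_quantile: float = 0.05, display_threshold: float = 0.5) -> IntegrationReport:
    """Full integration report for one pair of tissues."""
    overlap = module_overlap(partition_muscle, partition_blood)
    csv_b_in_m, per_mod_b = csv_index(partition_blood, net_blood, net_muscle, edge_quantile)
    csv_m_in_b, per_mod_m = csv_index(partition_muscle, net_muscle, net_blood, edge_quantile)
    per_mod_b.insert(0, "direction", "blood_modules_in_muscle_network")
    per_mod_m.insert(0, "direction", "muscle_modules_in_blood_network")
    cross = eigengene_cross_correlation(partition_blood.eigengenes,
                                        partition_muscle.eigengenes,
                                        matched_idx_blood, matched_idx_muscle,
                                        display_threshold)
    sensors = hub_sensor_scan(blood_expr, partition_blood.gene_ids, hubs,
                              partition_muscle.eigengenes,
                              matched_idx_blood, matched_idx_muscle)
    return IntegrationReport(
        module_overlap=overlap,
        csv_blood_in_muscle=csv_b_in_m,
        csv_muscle_in_blood=csv_m_in_b,
        csv_per_module=pd.concat([per_mod_b, per_mod_m], ignore_index=True),
        eigengene_correlation=cross,
        hub_sensors=sensors,
    )
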