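"""Treatment-response analysis of the three-arm antisense experiment.

Re-runs the longitudinal blood analysis to obtain the week-12 disease gene
list and its estimated logFCs, then fits NB GLMs across the saline / PMO-like
/ PS49-like arms on that list: QLF omnibus and pairwise tests, and a
desired-effect concordance score (the desired effect of a restorative drug is
the opposite of the disease logFC).  The PS49-like arm carries a planted
side-effect signature, so its pairwise test should light up while the
modest-restoration PMO-like arm shows directional movement without formal
significance.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dystromon import de_mixed, nbglm, normalize, simulate, voom
from dystromon.core_io import write_results


def week12_disease_list(seed, screen_fdr=0.05):
    """Genes significant at week 12 (LRT screen AND Wald) with their
    estimated logFCs, from the longitudinal pipeline."""
    design = simulate.molong_design(seed=seed)
    cm, st, _ = simulate.simulate_longitudinal(design)
    keep = st[st["group"].isin(["WT", "mdx"])]
    cm2 = cm.subset_samples(list(keep["sample_id"]))
    ne = normalize.normalize(cm2)
    X_alt, _, _, _, _ = de_mixed.build_designs(keep, ref_group="WT")
    pw = voom.voom(ne.logcpm, X_alt, ne.eff_lib_sizes)
    res = de_mixed.longitudinal_de(ne.logcpm, pw.weights, keep, ne.gene_ids,
                                   ref_group="WT", screen_fdr=screen_fdr)
    wald12 = res.wald[12].set_index("gene_id")
    sig = res.significant(12)
    # disease logFC: mdx vs WT; the desired drug effect is its opposite
    return sig, wald12.loc[sig, "logFC"].rename("disease_logfc")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=13154)
    ap.add_argument("--out-dir", type=Path, default=Path("results/treatment"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    gene_list, disease_logfc = week12_disease_list(args.seed)
    print(f"week-12 disease gene list: {len(gene_list)} genes")

    d_long = simulate.molong_design(seed=args.seed)
    _, _, truth_l = simulate.simulate_longitudinal(d_long)
    d_tr = simulate.motreat_design(seed=args.seed + 1)
    cm, st, truth_t = simulate.simulate_treatment(d_tr, truth_l)
    rep = nbglm.treatment_analysis(cm, st, gene_list, disease_logfc)

    print(f"analyzed {len(rep.analyzed_genes)} of {rep.n_requested} listed genes "
          f"({rep.n_dropped_by_filter} dropped by the expression filter)")
    print(f"{rep.n_concordant} genes concordant with the desired treatment "
          f"effect in both arms")
    n_omni = int((rep.omnibus["adj_p"] < 0.05).sum())
    print(f"QLF omnibus: {n_omni} genes significant at FDR<0.05")
    for arm, tab in rep.pairwise.items():
        n = int((tab["adj_p"] < 0.05).sum())
        print(f"  {arm} vs saline: {n} significant")

    write_results(rep.omnibus, args.out_dir / "omnibus.tsv")
    for arm, tab in rep.pairwise.items():
        write_results(tab, args.out_dir / f"{arm}_vs_saline.tsv")
    conc = pd.DataFrame({
        "gene_id": rep.analyzed_genes,
        "desired_effect": rep.desired_effect.to_numpy(),
        "PMO_logfc": rep.arm_logfc["PMO"].to_numpy(),
        "PS49_logfc": rep.arm_logfc["PS49"].to_numpy(),
        "concordant": rep.concordant.to_numpy(),
    })
    write_results(conc, args.out_dir / "concordance.tsv", sort_by=["gene_id"])


if __name__ == "__main__":
    main()
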