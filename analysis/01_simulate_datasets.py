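"""Generate the four synthetic study datasets with known ground truth.

Writes counts, sample metadata, covariate blocks and planted-truth tables for
the cross-sectional muscle cohort (paired with blood), the longitudinal blood
cohort, the three-arm treatment experiment, and the human patient cohort.
"""

import argparse
from pathlib import Path

import pandas as pd

from dystromon import simulate
from dystromon.core_io import write_counts


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=13154)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    d_mus = simulate.momus_design(seed=args.seed)
    (mcm, mst, mtruth), (bcm, bst, btruth) = simulate.simulate_paired_tissues(d_mus)
    for name, cm, st in (("muscle", mcm, mst), ("blood_wk30", bcm, bst)):
        write_counts(cm, out / f"{name}_counts.tsv")
        st.to_csv(out / f"{name}_samples.tsv", sep="\t", index=False)
    mtruth.logfc.rename_axis("gene_id").to_csv(out / "muscle_true_logfc.tsv", sep="\t")

    d_long = simulate.molong_design(seed=args.seed)
    lcm, lst, ltruth = simulate.simulate_longitudinal(d_long)
    write_counts(lcm, out / "blood_long_counts.tsv")
    lst.to_csv(out / "blood_long_samples.tsv", sep="\t", index=False)
    ltruth.logfc.rename_axis("gene_id").to_csv(out / "blood_long_true_logfc.tsv", sep="\t")

    d_tr = simulate.motreat_design(seed=args.seed + 1)
    tcm, tst, ttruth = simulate.simulate_treatment(d_tr, ltruth)
    write_counts(tcm, out / "treatment_counts.tsv")
    tst.to_csv(out / "treatment_samples.tsv", sep="\t", index=False)

    d_co = simulate.dmdmex_design(seed=args.seed + 2)
    ccm, cst, blocks, ctruth = simulate.simulate_cohort(d_co)
    write_counts(ccm, out / "cohort_counts.tsv")
    cst.to_csv(out / "cohort_samples.tsv", sep="\t", index=False)
    blocks["body"].rename_axis("sample_id").to_csv(out / "cohort_body_block.tsv", sep="\t")
    blocks["physical"].rename_axis("sample_id").to_csv(out / "cohort_physical_block.tsv", sep="\t")

    print(f"wrote synthetic datasets to {out}/")
    print(f"  muscle: {mcm.shape[0]} genes x {mcm.shape[1]} samples "
          f"({len(mtruth.de_genes)} planted disease genes, "
          f"{len(d_mus.modules.sizes)} planted modules)")
    print(f"  longitudinal blood: {lcm.shape[1]} samples over {len(d_long.timepoints)} weeks")
    print(f"  treatment: {tcm.shape[1]} mice in 3 arms "
          f"({len(ttruth.concordant_genes)} truly concordant genes)")
    print(f"  cohort: {ccm.shape[1]} subjects "
          f"(anchor gene {ctruth.anchor_gene} tied to the physical-test factor)")


if __name__ == "__main__":
    main()
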