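#!/usr/bin/env python
"""Statistical battery over the feature spaces: pairwise PERMANOVA and
PERMDISP with BH-FDR, stratified random-forest balanced accuracy, and
per-gene ridge regression from the stain-derived latent."""

import argparse
from pathlib import Path

import pandas as pd

from stvae.cluster import standardize
from stvae.stats import (pairwise_permanova, pairwise_permdisp,
                         rf_cv_balanced_accuracy, ridge_predict_genes)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pre", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--latents", type=Path, default=Path("results/latents"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-trees", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    labels_df = pd.read_csv(args.pre / "labels.csv").set_index("cell")
    counts = pd.read_csv(args.pre / "counts_lognorm.csv").set_index("cell")
    frames = {"tc": counts}
    for name in ("tc", "stains"):
        path = args.latents / f"latent_{name}.csv"
        if path.exists():
            frames[f"latent_{name}"] = pd.read_csv(path).set_index("cell")
    common = labels_df.index
    for df in frames.values():
        common = common.intersection(df.index)
    common = common.sort_values()
    labels = labels_df.loc[common, "label"].to_numpy()
    counts = counts.loc[common]
    spaces = {name: df.loc[common].to_numpy() for name, df in frames.items()}

    for name, X in spaces.items():
        Xs = standardize(X)
        pa = pairwise_permanova(Xs, labels, n_perm=999, seed=args.seed)
        pdp = pairwise_permdisp(Xs, labels, n_perm=999, seed=args.seed)
        pa.to_csv(args.out / f"permanova_{name}.csv", index=False)
        pdp.to_csv(args.out / f"permdisp_{name}.csv", index=False)
        ba = rf_cv_balanced_accuracy(Xs, labels, n_trees=args.n_trees,
                                     seed=args.seed)
        ba.to_csv(args.out / f"balanced_accuracy_{name}.csv", index=False)
        print(f"{name:14s} significant pairs (q<0.05): "
              f"{(pa['q'] < 0.05).sum()}/{len(pa)} location, "
              f"{(pdp['q'] < 0.05).sum()}/{len(pdp)} dispersion; "
              f"mean balanced accuracy {ba['balanced_accuracy'].mean():.3f}")

    if "latent_stains" in spaces:
        tab = ridge_predict_genes(spaces["latent_stains"], counts.to_numpy(),
                                  gene_names=list(counts.columns),
                                  alpha=1.0, seed=args.seed)
        tab = tab.sort_values("r2_test", ascending=False)
        tab.to_csv(args.out / "ridge_latent_stains.csv", index=False)
        top = tab.head(3)
        print("top genes predictable from the stain latent:")
        for _, row in top.iterrows():
            print(f"  {row['gene']}: R2={row['r2_test']:.3f} "
                  f"q={row['min_q_f_test']:.2e}")


if __name__ == "__main__":
    main()
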