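#!/usr/bin/env python
"""Cluster each feature space (counts, latents, classical features) with
tuned Leiden, then multiplex counts with the stain latent, and score
everything against ground truth (homogeneity, AMI, matched Jaccard)."""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from stvae.cluster import (clustering_metrics, jaccard_match,
                           tune_multiplex_weights, tune_single)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pre", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--latents", type=Path, default=Path("results/latents"))
    ap.add_argument("--features", type=Path, default=Path("results/features"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/clustering"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    labels_df = pd.read_csv(args.pre / "labels.csv").set_index("cell")
    frames = {"tc": pd.read_csv(args.pre / "counts_lognorm.csv"
                                ).set_index("cell")}
    for name in ("tc", "stains"):
        path = args.latents / f"latent_{name}.csv"
        if path.exists():
            frames[f"latent_{name}"] = pd.read_csv(path).set_index("cell")
    for path in sorted(args.features.glob("classical_*px.csv")):
        frames[path.stem] = pd.read_csv(path, index_col=0)

    # feature spaces may cover slightly different cell sets (filtering);
    # evaluate on the common cells
    common = labels_df.index
    for df in frames.values():
        common = common.intersection(df.index)
    common = common.sort_values()
    truth = labels_df.loc[common, "label"].to_numpy()
    spaces = {name: df.loc[common].to_numpy() for name, df in frames.items()}

    summary = {}
    tuned = {}
    for name, X in spaces.items():
        cr = tune_single(X, k_grid=(10, 15, 30), min_clusters=4,
                         seed=args.seed)
        met = clustering_metrics(cr.labels, truth, X, seed=args.seed)
        jac = jaccard_match(cr.labels, truth)
        tuned[name] = cr
        summary[name] = {
            "k": cr.k, "resolution": cr.resolution,
            "n_clusters": cr.n_clusters,
            "silhouette": met["silhouette"],
            "homogeneity": met["homogeneity"], "ami": met["ami"],
            "matched_jaccard_total": jac.total_score,
        }
        print(f"{name:18s} k={cr.k:<3} res={cr.resolution:<5} "
              f"clusters={cr.n_clusters:<3} homog={met['homogeneity']:.3f} "
              f"ami={met['ami']:.3f}")

    if "latent_stains" in spaces:
        mres = tune_multiplex_weights(
            [spaces["tc"], spaces["latent_stains"]],
            inherited=[(tuned["tc"].k, tuned["tc"].resolution),
                       (tuned["latent_stains"].k,
                        tuned["latent_stains"].resolution)],
            min_clusters=4, seed=args.seed)
        met = clustering_metrics(mres.labels, truth)
        summary["tc+latent_stains"] = {
            "weights_percent": list(mres.metrics["weights_percent"]),
            "n_clusters": mres.n_clusters,
            "homogeneity": met["homogeneity"], "ami": met["ami"],
        }
        print(f"tc+latent_stains   weights={mres.metrics['weights_percent']} "
              f"clusters={mres.n_clusters} homog={met['homogeneity']:.3f}")

    (args.out / "clustering_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    for name, cr in tuned.items():
        np.savetxt(args.out / f"assignments_{name}.csv", cr.labels, fmt="%d")


if __name__ == "__main__":
    main()
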