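"""Desk-scale benchmark experiments run end-to-end on synthetic tissue.

Two experiments anchor the pipeline's validation:

* **Type recovery** — a 600-cell, 4-type, 20-gene tissue with strongly
  type-specific morphology and marker programs; the transcripts-only and
  stains-only VAEs are each trained for 15 epochs and their posterior-sampled
  latents are Leiden-clustered against ground truth.
* **Multiplex gain** — a tissue in which two types share one transcriptional
  program but differ morphologically; transcript counts alone cannot split
  the pair, and multiplex Leiden clustering of counts with the stain-derived
  latent must strictly raise cluster homogeneity.

Problem sizes are chosen so each experiment runs in minutes on one CPU while
keeping the structure of the full-scale analysis (imbalanced types, sparse
counts, layered tissue, bounding-box crops).
"""

from __future__ import annotations

import numpy as np

from .cluster import (build_knn_graph, clustering_metrics, leiden_cluster,
                      standardize, tune_multiplex_weights)
from .preprocess import CountMatrixView, build_multiplane_crop, \
    extract_stain_crop, normalize_counts
from .synthetic import MorphologyParams, SpatialDataset, SynthConfig, \
    generate_dataset
from .vae import VAE, VAEConfig, extract_latent, train

__all__ = [
    "strong_morphologies",
    "recovery_config",
    "shared_program_config",
    "tc_model_config",
    "stain_model_config",
    "build_crops",
    "latent_homogeneity",
    "run_recovery",
    "run_multiplex_gain",
]

CROP = 64
N_GENES = 20


def strong_morphologies() -> list[MorphologyParams]:
    """Four clearly separated morphotypes: nucleus size, shape, intensity,
    membrane thickness and polarisation all differ."""
    return [
        MorphologyParams(nucleus_radius=5, eccentricity=0.0, membrane_width=1.5,
                         nucleus_intensity=0.4, membrane_intensity=1.2,
                         polarized=False),
        MorphologyParams(nucleus_radius=9, eccentricity=0.6, membrane_width=2.5,
                         nucleus_intensity=1.2, membrane_intensity=0.3,
                         polarized=True),
        MorphologyParams(nucleus_radius=13, eccentricity=0.0, membrane_width=4.0,
                         nucleus_intensity=0.7, membrane_intensity=0.9,
                         polarized=False),
        MorphologyParams(nucleus_radius=17, eccentricity=0.5, membrane_width=1.0,
                         nucleus_intensity=1.0, membrane_intensity=0.6,
                         polarized=True),
    ]


def recovery_config(seed: int = 3) -> SynthConfig:
    """600 cells, 4 imbalanced types, 20 genes all acting as type-exclusive
    markers, 75% count sparsity, 64-px crops."""
    return SynthConfig(
        n_cells=600, n_types=4, n_genes=N_GENES, abundance_skew=4.0,
        target_sparsity=0.75, image_size=1024, crop_size=CROP,
        markers_per_type=5, marker_fold=30.0,
        morphology=strong_morphologies(), seed=seed,
    )


def shared_program_config(seed: int = 3) -> SynthConfig:
    """As ``recovery_config`` but types 0 and 1 share one expression program
    while remaining morphologically distinct."""
    cfg = recovery_config(seed)
    cfg.shared_programs = {1: 0}
    return cfg


def tc_model_config(seed: int = 5, n_genes: int = N_GENES) -> VAEConfig:
    """Transcripts-only analog of the 100-px production model, shrunk to
    64-px crops / 4 conv blocks for CPU-scale runs."""
    return VAEConfig(modality="tc", n_genes=n_genes, crop_size=CROP,
                     n_conv_blocks=4, channels=(16, 32, 64, 128),
                     latent_dim=50, spot_padding=3, learning_rate=1e-3,
                     batch_size=8, epochs=15, seed=seed)


def stain_model_config(seed: int = 5) -> VAEConfig:
    """Stains-only analog (nuclear + membrane channels)."""
    return VAEConfig(modality="stains", crop_size=CROP, n_conv_blocks=4,
                     channels=(16, 32, 64, 128), latent_dim=50,
                     learning_rate=5e-4, batch_size=16, epochs=15, seed=seed)


def build_crops(ds: SpatialDataset, padding_p: int = 3,
                crop_size: int = CROP) -> tuple[np.ndarray, np.ndarray]:
    """Multi-plane TC crops and stain crops for every cell, in table order."""
    ids = ds.cells["cell"].to_numpy()
    genes = list(range(ds.n_genes))
    tc = np.stack([build_multiplane_crop(ds, c, crop_size, padding_p, genes).tensor
                   for c in ids])
    st = np.stack([extract_stain_crop(ds, c, crop_size).tensor for c in ids])
    return tc, st


def latent_homogeneity(latent_values: np.ndarray, truth: np.ndarray,
                       k: int = 15, resolution: float = 1.0,
                       seed: int = 0) -> dict:
    """Leiden (fixed validation defaults k=15, resolution=1) on a standardized
    latent, scored against truth and against a label-shuffled baseline."""
    X = standardize(latent_values)
    graph = build_knn_graph(X, k)
    cr = leiden_cluster(graph, resolution, seed=seed)
    met = clustering_metrics(cr.labels, truth, X, seed=seed)
    rng = np.random.default_rng([seed, 601])
    shuffled = clustering_metrics(cr.labels, rng.permutation(truth))
    return {
        "n_clusters": cr.n_clusters,
        "homogeneity": met["homogeneity"],
        "ami": met["ami"],
        "silhouette": met["silhouette"],
        "shuffled_homogeneity": shuffled["homogeneity"],
        "labels": cr.labels,
    }


def run_recovery(seed: int = 0, epochs: int = 15) -> dict:
    """Train the TC-only and stains-only models on the recovery benchmark and
    Leiden-cluster each posterior-sampled latent."""
    ds = generate_dataset(recovery_config(seed=seed * 2 + 3))
    truth = ds.cells["type"].to_numpy()
    tc, st = build_crops(ds)

    m_tc = VAE(tc_model_config(seed=seed * 2 + 5))
    m_tc.config.epochs = epochs
    train(m_tc, tc_crops=tc, counts=ds.counts)
    lat_tc = extract_latent(m_tc, tc_crops=tc, mode="posterior-sample",
                            seed=seed + 11)

    m_st = VAE(stain_model_config(seed=seed * 2 + 5))
    m_st.config.epochs = epochs
    train(m_st, stain_crops=st)
    lat_st = extract_latent(m_st, stain_crops=st, mode="posterior-sample",
                            seed=seed + 11)

    return {
        "tc": latent_homogeneity(lat_tc.values, truth, seed=seed),
        "stains": latent_homogeneity(lat_st.values, truth, seed=seed),
        "tc_log": m_tc.training_log,
        "stains_log": m_st.training_log,
        "dataset": ds,
        "tc_latent": lat_tc,
        "stain_latent": lat_st,
    }


def run_multiplex_gain(seed: int = 0, n_repeats: int = 3,
                       epochs: int = 15) -> dict:
    """Multiplex clustering of TC with the stain-derived latent, versus TC
    alone, on the shared-program tissue; repeated over ``n_repeats`` paired
    seeds."""
    ds = generate_dataset(shared_program_config(seed=seed * 2 + 3))
    truth = ds.cells["type"].to_numpy()
    _, st = build_crops(ds)
    counts_norm = normalize_counts(CountMatrixView(ds.counts)).values

    rows = []
    for rep in range(n_repeats):
        rep_seed = seed * 10 + rep
        m_st = VAE(stain_model_config(seed=rep_seed * 2 + 5))
        m_st.config.epochs = epochs
        train(m_st, stain_crops=st)
        lat = extract_latent(m_st, stain_crops=st, mode="posterior-sample",
                             seed=rep_seed + 11).values

        tc_only = latent_homogeneity(counts_norm, truth, seed=rep_seed)
        ls_only = latent_homogeneity(lat, truth, seed=rep_seed)
        # inherited per-layer defaults (validation settings), then weight scan
        mres = tune_multiplex_weights([counts_norm, lat],
                                      inherited=[(15, 1.0), (15, 1.0)],
                                      min_clusters=4, seed=rep_seed)
        met = clustering_metrics(mres.labels, truth)
        rows.append({
            "seed": rep_seed,
            "homogeneity_tc": tc_only["homogeneity"],
            "homogeneity_stain_latent": ls_only["homogeneity"],
            "homogeneity_multiplex": met["homogeneity"],
            "tc_weight_percent": mres.metrics["weights_percent"][0],
            "n_clusters_multiplex": mres.n_clusters,
        })
    return {"repeats": rows, "dataset": ds}
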