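# stvae

Multi-modal integration for imaging-based spatial transcriptomics:
variational-autoencoder embeddings of per-cell transcript-spot crops and
paired nuclear/membrane stain crops, evaluated alone and jointly with
transcript counts via multiplex Leiden clustering.

## The problem

Imaging-based spatial transcriptomics (e.g. MERFISH) yields, per cell, a
sparse cloud of decoded transcript spots *and* the morphology visible in
accompanying stains. Transcript counts (TC) dominate cell-type analysis, but
morphology carries complementary identity signal — especially under
real-world constraints: small datasets, strongly imbalanced cell types, and
bounding-box rather than precise segmentation. This package asks: can a
minimally tuned convolutional VAE extract useful low-dimensional latent
spaces (LS) from spot crops, stain crops, or both — and does *multiplex*
clustering of TC with a stain-derived LS improve cluster purity over TC
alone?

Cells are represented for the transcript model as multi-plane binary
tensors (one plane per gene, spots dilated to `(p+2) x (p+2)` patches),
framing reconstruction as sparse multi-class segmentation. The transcript
objective is per-gene soft Dice plus pixel focal loss, weighted 0.8 : 0.4,

    Dice = 1 - (2 |X ∩ Y|) / (|X| + |Y|),
    Focal = -alpha_t (1 - p_t)^gamma log p_t,

with inverse-expression gene weights (rescaled into [1, 10]) so rare genes
are not neglected; stains use plain L2; the KL term is off (beta = 0).
A shared encoder with one decoder per modality handles the multimodal case.
Downstream, latents are clustered with Leiden (single-layer or layered
multiplex graphs, hyperparameters tuned by silhouette under a minimum
cluster bound), and feature spaces are compared via pairwise PERMANOVA /
PERMDISP with BH-FDR, stratified random-forest balanced accuracy,
Hungarian-matched Jaccard scores, and per-gene ridge regression.

A seed-reproducible synthetic tissue generator (imbalanced types in spatial
bands, negative-binomial marker programs calibrated to a target sparsity,
rendered nuclear/membrane stains with type-dependent morphology) makes the
whole pipeline testable without any download. Since VAE training is in plain
numpy, everything runs on one CPU.

## Worked example

```python
from stvae.benchmarks import run_recovery

out = run_recovery(seed=1)            # ~2 minutes on one CPU
print(out["tc"]["homogeneity"], out["stains"]["homogeneity"])
```

This generates a 600-cell tissue (4 types spanning a 4-fold abundance range,
20 marker genes, 75% count sparsity, 64-px crops), trains the
transcripts-only and stains-only VAEs for 15 epochs each, and Leiden-clusters
each posterior-sampled 50-dimensional latent. With seed 1 it prints

```
0.6230... 0.9586...
```

meaning the transcript latent recovers the planted cell types with
homogeneity 0.62 and the stain latent with 0.96, versus < 0.01 for a
label-shuffled baseline (`out["tc"]["shuffled_homogeneity"]`). The multiplex
experiment, `run_multiplex_gain(seed=1)`, builds a tissue where two types
share an expression program but differ morphologically; transcript counts
alone plateau at homogeneity ≈ 0.60, while multiplex clustering with the
stain latent reaches ≈ 0.91 in every paired repeat.

The same steps are available as narrative scripts:

```
python analysis/01_simulate.py           # write synthetic tissues (CSV/MTX/TIFF)
python analysis/02_preprocess.py         # filters, normalisation, gene subsets
python analysis/03_train_vaes.py         # train VAEs, write latent CSVs
python analysis/04_classical_features.py # hand-crafted comparator features
python analysis/05_cluster.py            # tuned + multiplex Leiden, metrics
python analysis/06_stats.py              # PERMANOVA/PERMDISP, RF, ridge
python analysis/07_multiplex_gain.py     # the headline comparison
```

each writing its tables under `results/`.

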