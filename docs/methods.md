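# Methods

`stvae` studies a multi-modal integration question from imaging-based spatial
transcriptomics: given per-cell crops of decoded transcript spots and paired
nuclear/membrane stain images, how much cell-type signal do low-dimensional
VAE embeddings of each modality carry, and does jointly clustering transcript
counts (TC) with a stain-derived latent space improve label recovery? The
package implements the full chain — synthetic tissue generation, filtering
and normalisation, multi-plane crop construction, VAE training, classical
feature extraction, single and multiplex Leiden clustering, and a statistical
battery — so the question can be answered end-to-end on one CPU.

## Data representation

Cells are represented for the transcript VAE as multi-plane binary tensors:
one plane per gene, with each decoded spot expanded to a `(p+2) x (p+2)`
pixel patch (`p` is the spot padding; even kernels anchor the extra row and
column toward increasing indices, a convention chosen so the expansion is
deterministic). Crops are half-open windows `[c - s/2, c + s/2)` centred on
the floor of the cell centroid. Crops are bounding boxes, not masks: spots of
neighbouring cells inside the window are included, which mirrors the
bounding-box segmentation regime the pipeline targets. Windows that cross the
image border are zero-filled by default (a strict mode raises instead).

Counts are filtered (cells smaller than 50 px or with fewer than 10
transcripts removed; genes with fewer than 100 transcripts tissue-wide
removed — all strict inequalities, boundary values kept, and both filters
evaluated on raw totals frozen at ingestion so they commute), then scaled so
every cell's total equals the median cell total, then log1p-transformed.

## VAE

One architecture serves five configurations: transcripts-only, stains-only,
and three multimodal variants in which the TC planes and the two stain
channels are channel-concatenated into one encoder while two separate
decoders reconstruct each modality. Encoder blocks are convolution (kernel 3,
stride 2, no padding) -> leaky ReLU (slope 0.1) -> batch norm; decoders
mirror the chain with transposed convolutions, using per-block output padding
to reproduce the exact encoder size chain (100 -> 49 -> 24 -> 11 -> 5 -> 2
at five blocks; the minimum admissible crop for `n` blocks is `2^(n+1) - 1`).
The latent head produces a 50-dimensional mean and log-variance; training
samples `z = mu + sigma * eps`.

The transcript objective combines per-gene-plane soft Dice (smoothing 1.0 so
empty planes are well-defined) and pixel focal loss, weighted 0.8 : 0.4
applied literally (not renormalised). Focal `alpha` defaults to 0.25, the
standard value from the focal-loss literature; `gamma` defaults to 2. Stain
reconstruction uses plain mean-squared error (weight 1.0 by default; logged
separately per epoch so modality imbalance is visible). The KL term is
scaled by `beta_kl` and is 0 by default: the latent is consumed by downstream
analyses, so reconstruction fidelity is prioritised over posterior
regularisation.

Dynamic gene weighting counteracts the bias toward highly expressed genes:
per cell, a gene's weight is the inverse of its expression (with a +1
pseudocount), rescaled to the cell's total count; weights are averaged per
batch (or per class when labels are supplied), projected onto the
anti-monotone cone (weights non-increasing in batch expression, via
pool-adjacent-violators — per-cell averaging alone does not guarantee this),
and min-max rescaled into [1, 10].

Training is transductive — every cell is in the training set, since the goal
is a representation of those very cells — with random orthogonal rotation
(uniform over 0/90/180/270 degrees, identical across planes and modalities
of a cell) as the only augmentation. Optimisation uses Adam; because nothing
bounds the posterior parameters at `beta_kl = 0`, training clips the global
gradient norm at 5 and clamps log-variances to [-8, 8]. The sigmoid output
layer of the transcript decoder starts at a bias of -4 (foreground prior
about 2%), so short training runs are spent on signal rather than on learning
that the planes are mostly background. Latents are extracted in batch-norm
evaluation mode, either as a single seeded posterior draw (the default,
matching the study design) or as the posterior mean.

The engine itself (`stvae.nn`) is a compact CPU-native implementation of
strided valid convolutions (im2col), transposed convolutions, batch norm,
dense layers and Adam with explicit backprop, in float32; its gradients are
tested against central finite differences.

## Classical comparator

`stvae.features` plays the role of a hand-crafted morphological profiler on
the same dual-channel crops: per channel it measures intensity summaries
(mean, sd, quartiles, mass displacement), radial intensity fractions in four
annuli, gray-level co-occurrence texture (contrast, correlation, entropy at
offsets 1 and 3 px, four directions averaged, 32 gray levels) and a
granularity spectrum from eight successive morphological openings. It makes
no claim of numerical parity with any external profiling tool — the feature
definitions above are the pinned, reproducible reference. Selection runs
drop-NA -> blocklist -> variance threshold -> correlation threshold; from
each over-correlated pair the member with the larger mean |r| to the other
features is dropped, ties by name order, which makes selection idempotent.

## Clustering and evaluation

Feature spaces are z-scored (population sd; constant columns map to zero with
a warning) before graph construction. k-NN graphs are symmetrised unions with
Euclidean distances and stable index tie-breaking; Leiden clustering uses the
RB-configuration modularity at resolution gamma, and single-layer clustering
is routed through the same multiplex optimiser code path so that a one-layer
multiplex run is exactly the single-layer result. Hyperparameters are tuned
by grid search (default k in {10, 15, 20, 30, 50}, gamma in {0.1 ... 2.0})
maximising mean silhouette subject to a minimum cluster count of 5; fixed
defaults (k=15, gamma=1) are used for quick validation runs. Multiplex weight
tuning inherits per-layer (k, gamma) from the single-layer optima and scans
the two-layer weight simplex in 0.05 steps, scoring each candidate partition
by the unweighted mean of its per-modality silhouettes (the space of that
silhouette is a genuine design choice; a concatenated-space variant would be
a one-line change). Exact objective ties across weightings resolve toward
the purest weighting so an uninformative layer is never credited. Silhouette
computations subsample to at most 5,000 cells, seeded.

External validation uses homogeneity, adjusted mutual information, and
per-pair Jaccard scores matched one-to-one by the Hungarian algorithm
(maximising total Jaccard; unmatched labels and clusters are reported).

## Statistics

Pairwise PERMANOVA uses Anderson's pseudo-F computed from the pairwise
Euclidean squared-distance matrix in sums-of-squared-distances form, with
999 free permutations of the pooled pair (vectorised; pairs small enough are
enumerated exactly), and BH-FDR across pairs. PERMDISP computes each point's
distance to its group's arithmetic centroid and runs a permutation ANOVA on
those residuals. Permutation p-values are `(#{F >= F_obs} + 1) / (n_perm+1)`.
Classification uses a 1,000-tree random forest with balanced class weights
in stratified 5-fold CV, reporting per-class recall averaged over folds.
Per-gene ridge regression (alpha = 1, 80/20 split) predicts each gene from
the latent matrix on standardized predictors with an unpenalised intercept;
significance is the minimum BH-adjusted univariate F-test p over latent
variables, adjusted jointly across all gene x latent tests.

## Synthetic tissue generator

The generator emulates the structure of the targeted MERFISH section rather
than its optics: defaults are 5,192 cells of 19 types whose abundances follow
a geometric profile spanning a 40-fold range, 241 genes with an 89.62% sparse
count matrix, layered tissue (one horizontal band per type), and 100-px
crops. Counts are negative-binomial (dispersion theta = 2 by default) with
per-type marker programs; a global scale is bisected so the expected zero
fraction hits the target, followed by binomial thinning on the realised
matrix if needed (error if the target is unreachable within +/-0.05). Every
counted transcript is materialised as a spot uniform in its cell's ellipse,
so the count-matrix/spot-table identity is exact by construction. Stains are
rendered as blurred nuclear ellipses and membrane rings (optionally
polarised to one side, emulating basolateral staining) with additive
Gaussian noise. Centroids are placed by rejection sampling with pairwise
minimum distances equal to the sum of nucleus radii (nuclei disjoint,
membranes may touch), at least half a crop from the border by default.

What the generator does **not** emulate: realistic point-spread functions,
segmentation errors, 3D structure, gene-gene correlation beyond the type
programs, or spatial expression gradients within a band. Passing tests
therefore demonstrate that the pipeline recovers structure it is pointed at,
not that it would perform identically on real tissue.

## Benchmark experiments and problem sizes

Two desk-scale experiments (in `stvae.benchmarks`) anchor validation, sized
to run in minutes on one CPU:

* **Type recovery** — 600 cells, 4 types (abundance skew 4), 20 genes all
  serving as type-exclusive markers (5 per type, 30-fold elevation, 75%
  sparsity), 64-px crops, strongly separated morphotypes (nucleus radius
  5/9/13/17 px with distinct eccentricity, intensity, membrane width and
  polarisation). The transcripts-only model (4 conv blocks, channels
  16-128, lr 1e-3, batch 8) and the stains-only model (lr 5e-4, batch 16)
  each train 15 epochs; Leiden (k=15, gamma=1) on each posterior-sampled
  latent recovers the types with homogeneity well above 0.5 while a
  label-shuffled baseline stays near zero. These runs keep gene weighting on
  and otherwise use the production loss settings.
* **Multiplex gain** — the same tissue except types 0 and 1 share one
  expression program. Counts alone cannot split the pair (homogeneity
  plateaus near 0.6); multiplex Leiden of counts with the stain latent,
  weight-tuned on the simplex, separates it (homogeneity ~0.9), in every one
  of three paired repeats.

The permutation-test calibration uses 200 null simulations of two 20-cell
groups in 5 dimensions with 999 permutations each; regression recovery uses
n = 1,000 cells with a 10-dimensional latent.

## Known limitations

* The numpy engine is single-threaded-friendly but far slower than a GPU
  framework; production-scale runs (5,192 cells, 241 planes, 100-300 px
  crops, hundreds of epochs) are supported by the code but not by desk-scale
  time budgets.
* With `beta_kl = 0` the latent scale is unconstrained; gradient clipping
  and the log-variance clamp make training reliable, but latent geometry
  across seeds varies more than for a regularised VAE.
* Leiden at default resolution on k-NN graphs of compact blobs can split
  large homogeneous groups; the tuning grid (silhouette objective, minimum
  cluster bound) is the intended interface, and fixed (k=15, gamma=1) is a
  validation convenience.
* The classical-feature module reproduces the *role* of an external
  profiling pipeline, not its numbers; cross-study feature comparisons
  should treat the two as different feature families.
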