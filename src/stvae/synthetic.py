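"""Seed-reproducible synthetic MERFISH-like tissue generator.

Emulates the statistical structure of an imaging-based spatial-transcriptomics
section: a small number of strongly imbalanced cell types arranged in spatial
bands, a sparse cells x genes count matrix with per-type marker programs,
per-transcript decoded "spots" inside each cell, and paired nuclear / membrane
stain channels with type-dependent morphology.

Coordinates are 0-based pixels, origin top-left, ``x`` = column, ``y`` = row;
bounding boxes are half-open ``[x0, x1) x [y0, y1)``. Distributional choices
(negative-binomial counts, Gaussian blur + noise for stains) are stand-ins
chosen as field-standard defaults and are flagged as such in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "MorphologyParams",
    "SynthConfig",
    "SpatialDataset",
    "simulate_cells",
    "simulate_transcripts",
    "render_stains",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]

# substreams so each stage has its own reproducible rng
_STAGE_CELLS, _STAGE_COUNTS, _STAGE_STAINS = 11, 13, 17


@dataclass
class MorphologyParams:
    """Per-type stain morphology (pixel units)."""

    nucleus_radius: float = 6.0
    eccentricity: float = 0.0          # 0 = circle, towards 1 = elongated
    membrane_width: float = 2.0
    nucleus_intensity: float = 1.0
    membrane_intensity: float = 0.8
    polarized: bool = False            # one-sided (basolateral-like) membrane stain


@dataclass
class SynthConfig:
    """Defaults emulate the murine-ileum section the pipeline targets: ~5200
    annotated cells of 19 types whose abundances span a 40-fold range, 241
    genes with a ~89.6% sparse count matrix, and 100-px bounding-box crops.
    Tests and desk-scale runs pass explicit smaller values."""

    n_cells: int = 5192
    n_types: int = 19
    n_genes: int = 241
    abundance_skew: float = 40.0       # max/min type-frequency ratio
    target_sparsity: float = 0.8962    # zero fraction of the count matrix
    mean_transcripts_per_cell: float = 60.0
    image_size: int = 2048
    crop_size: int = 100
    markers_per_type: int = 3
    marker_fold: float = 10.0          # marker elevation over background
    nb_dispersion: float = 2.0
    cell_radius_factor: float = 2.2    # cell ellipse = factor x nucleus ellipse
    noise_level: float = 0.02
    blur_sigma: float = 1.0
    layered: bool = True               # horizontal bands, one per type
    allow_border_cells: bool = False
    morphology: list[MorphologyParams] = field(default_factory=list)
    # map type -> type whose expression program it reuses (morphology differs);
    # used to emulate transcriptionally identical but morphologically distinct types
    shared_programs: dict[int, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if self.abundance_skew < 1:
            raise ValueError("abundance_skew must be >= 1")
        if not 0.0 < self.target_sparsity < 1.0:
            raise ValueError("target_sparsity must be in (0, 1)")
        if self.image_size < self.crop_size:
            raise ValueError("image_size must be >= crop_size")
        if not self.morphology:
            # spread radii/eccentricities so types are morphologically distinct
            radii = np.linspace(4.0, 12.0, self.n_types)
            self.morphology = [
                MorphologyParams(
                    nucleus_radius=float(r),
                    eccentricity=0.15 * (i % 3),
                    membrane_width=1.5 + 0.5 * (i % 4),
                    polarized=(i % 2 == 1),
                )
                for i, r in enumerate(radii)
            ]
        if len(self.morphology) != self.n_types:
            raise ValueError("morphology must have one entry per type")


@dataclass
class SpatialDataset:
    """Common substrate of all pipeline stages.

    ``cells``: DataFrame (cell, x, y, type, label, area, x0, y0, x1, y1).
    ``spots``: DataFrame (x, y, gene, cell); ``gene`` indexes ``genes``.
    ``counts``: cells x genes integer matrix aligned with ``cells`` row order.
    ``stains``: (2, H, W) float array, channel 0 nuclear, channel 1 membrane.
    """

    cells: pd.DataFrame
    genes: list[str] = field(default_factory=list)
    spots: pd.DataFrame | None = None
    counts: np.ndarray | None = None
    stains: np.ndarray | None = None
    image_size: int = 0
    # totals frozen at ingestion so filters commute (see preprocess)
    ingested_cell_totals: np.ndarray | None = None
    ingested_gene_totals: np.ndarray | None = None
    _scaled_stains: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def cell_row(self, cell_id: int) -> int:
        idx = np.flatnonzero(self.cells["cell"].to_numpy() == cell_id)
        if idx.size == 0:
            raise KeyError(f"unknown cell id {cell_id}")
        return int(idx[0])

    def scaled_stains(self) -> np.ndarray:
        """Stain stack min-max scaled to [0, 1] per channel over the whole image."""
        if self.stains is None:
            raise ValueError("dataset has no stain images")
        if self._scaled_stains is None:
            lo = self.stains.min(axis=(1, 2), keepdims=True)
            hi = self.stains.max(axis=(1, 2), keepdims=True)
            rng_ = np.where(hi - lo > 0, hi - lo, 1.0)
            self._scaled_stains = ((self.stains - lo) / rng_).astype(np.float32)
        return self._scaled_stains

    def check_consistency(self) -> None:
        """Assert the spot-table / count-matrix invariant exactly."""
        if self.spots is None or self.counts is None:
            return
        ids = self.cells["cell"].to_numpy()
        row_of = {c: i for i, c in enumerate(ids)}
        rebuilt = np.zeros_like(self.counts)
        if len(self.spots):
            for c, g in zip(self.spots["cell"].to_numpy(), self.spots["gene"].to_numpy()):
                rebuilt[row_of[c], g] += 1
        if not np.array_equal(rebuilt, self.counts):
            raise AssertionError("spot table and count matrix are inconsistent")


def _type_frequencies(n_types: int, skew: float) -> np.ndarray:
    """Geometric abundance profile with max/min ratio ``skew``."""
    if skew == 1.0:
        return np.full(n_types, 1.0 / n_types)
    r = skew ** (-1.0 / (n_types - 1))
    f = r ** np.arange(n_types)
    return f / f.sum()


def _cell_axes(cfg: SynthConfig, t: int) -> tuple[float, float]:
    m = cfg.morphology[t]
    a = cfg.cell_radius_factor * m.nucleus_radius
    b = a * np.sqrt(max(1.0 - m.eccentricity ** 2, 0.05))
    return a, b


def simulate_cells(config: SynthConfig) -> SpatialDataset:
    """Place typed cells in spatial bands with non-overlapping centroids."""
    rng = np.random.default_rng([config.seed, _STAGE_CELLS])
    n, size = config.n_cells, config.image_size
    margin = 0 if config.allow_border_cells else config.crop_size // 2
    usable = size - 2 * margin
    if usable <= 0:
        raise ValueError("image_size too small for the border margin")

    freqs = _type_frequencies(config.n_types, config.abundance_skew)
    counts = np.maximum(np.round(freqs * n).astype(int), 1)
    # fix rounding drift on the most abundant type
    counts[np.argmax(counts)] += n - counts.sum()
    types = np.repeat(np.arange(config.n_types), counts)

    # nuclei must stay disjoint; membranes may touch. Spacing is pairwise:
    # centroids at least the sum of the two nucleus radii apart.
    radii_by_type = np.array([m.nucleus_radius for m in config.morphology])
    if np.sum(np.pi * radii_by_type[types] ** 2) > 0.5 * usable * usable:
        raise ValueError(
            f"infeasible packing: {n} cells exceed half the usable area of an "
            f"image of size {size}"
        )

    # spatial bands along y (one per type) when layered
    xs = np.empty(n)
    ys = np.empty(n)
    placed_x: list[float] = []
    placed_y: list[float] = []
    band_h = usable / config.n_types
    cell_grid = max(2.0 * radii_by_type.max(), 1.0)
    placed_r: list[float] = []

    # grid-bucketed rejection sampling
    buckets: dict[tuple[int, int], list[int]] = {}

    def near(x, y, r):
        bx, by = int(x // cell_grid), int(y // cell_grid)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in buckets.get((bx + dx, by + dy), ()):
                    d = placed_r[j] + r
                    if (placed_x[j] - x) ** 2 + (placed_y[j] - y) ** 2 < d * d:
                        return True
        return False

    for i, t in enumerate(types):
        if config.layered:
            y_lo = margin + t * band_h
            y_hi = margin + (t + 1) * band_h
        else:
            y_lo, y_hi = margin, size - margin
        r_i = radii_by_type[t]
        ok = False
        for _ in range(2000):
            x = rng.uniform(margin, size - margin)
            y = rng.uniform(y_lo, y_hi)
            if not near(x, y, r_i):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"infeasible packing: could not place cell {i} after 2000 attempts"
            )
        placed_x.append(x)
        placed_y.append(y)
        placed_r.append(r_i)
        buckets.setdefault((int(x // cell_grid), int(y // cell_grid)), []).append(i)
        xs[i], ys[i] = x, y

    areas = np.array([np.pi * np.prod(_cell_axes(config, t)) for t in types])
    half = config.crop_size // 2
    cx, cy = np.floor(xs).astype(int), np.floor(ys).astype(int)
    cells = pd.DataFrame(
        {
            "cell": np.arange(n),
            "x": xs,
            "y": ys,
            "type": types,
            "label": [f"type_{t}" for t in types],
            "area": areas,
            "x0": cx - half,
            "y0": cy - half,
            "x1": cx - half + config.crop_size,
            "y1": cy - half + config.crop_size,
        }
    )
    return SpatialDataset(cells=cells, genes=[f"gene_{g}" for g in range(config.n_genes)],
                          image_size=size)


def _expression_programs(config: SynthConfig) -> np.ndarray:
    """Per-type mean expression (types x genes), before sparsity calibration.

    Each type gets ``markers_per_type`` exclusive marker genes elevated
    ``marker_fold`` over a flat background; background level is solved later.
    """
    need = config.n_types * config.markers_per_type
    if need > config.n_genes:
        raise ValueError(
            f"need {need} marker genes but only {config.n_genes} genes configured"
        )
    mu = np.ones((config.n_types, config.n_genes))
    for t in range(config.n_types):
        src = config.shared_programs.get(t, t)
        lo = src * config.markers_per_type
        mu[t, lo:lo + config.markers_per_type] = config.marker_fold
    return mu


def _nb_zero_fraction(mu: np.ndarray, theta: float) -> float:
    return float(np.mean((theta / (theta + mu)) ** theta))


def simulate_transcripts(dataset: SpatialDataset, config: SynthConfig) -> SpatialDataset:
    """Draw negative-binomial counts per cell, calibrated to the target zero
    fraction, and materialise each counted transcript as a spot inside the
    cell ellipse."""
    rng = np.random.default_rng([config.seed, _STAGE_COUNTS])
    types = dataset.cells["type"].to_numpy()
    profile = _expression_programs(config)

    # bisect a global scale so the expected NB zero fraction hits the target
    theta = config.nb_dispersion
    weights = np.bincount(types, minlength=config.n_types).astype(float)
    weights /= weights.sum()

    def expected_zero(scale):
        mus = profile * scale
        return float(np.sum(weights * np.array(
            [_nb_zero_fraction(mus[t], theta) for t in range(config.n_types)])))

    lo, hi = 1e-6, 1e4
    if expected_zero(lo) < config.target_sparsity:
        raise ValueError("target_sparsity unreachable given marker design")
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if expected_zero(mid) > config.target_sparsity:
            lo = mid
        else:
            hi = mid
    scale = np.sqrt(lo * hi)
    mus = profile * scale
    # rescale towards the requested per-cell depth while preserving the
    # marker/background ratio only if depth dominates (sparsity has priority)
    mean_total = float(np.sum(weights * mus.sum(axis=1)))
    if mean_total > 4.0 * config.mean_transcripts_per_cell:
        mus *= config.mean_transcripts_per_cell / mean_total

    mu_cells = mus[types]                                   # (n_cells, n_genes)
    p = theta / (theta + mu_cells)
    counts = rng.negative_binomial(theta, p).astype(np.int64)

    # binomial thinning towards the target zero fraction if the draw fell short
    realized = float(np.mean(counts == 0))
    if realized < config.target_sparsity - 0.01:
        lo_q, hi_q = 0.0, 1.0
        base = counts.copy()
        for it in range(25):
            q = 0.5 * (lo_q + hi_q)
            r2 = np.random.default_rng([config.seed, _STAGE_COUNTS, 100 + it])
            cand = r2.binomial(base, q)
            z = float(np.mean(cand == 0))
            if z > config.target_sparsity:
                lo_q = q
            else:
                hi_q = q
            if abs(z - config.target_sparsity) < 0.005:
                break
        counts = cand
        realized = float(np.mean(counts == 0))
    if abs(realized - config.target_sparsity) > 0.05:
        raise ValueError(
            f"target_sparsity unreachable: realized {realized:.3f} vs "
            f"target {config.target_sparsity:.3f}"
        )

    # materialise spots uniformly inside each cell's ellipse
    n_spots = int(counts.sum())
    sx = np.empty(n_spots)
    sy = np.empty(n_spots)
    sg = np.empty(n_spots, dtype=np.int64)
    sc = np.empty(n_spots, dtype=np.int64)
    pos = 0
    xs = dataset.cells["x"].to_numpy()
    ys = dataset.cells["y"].to_numpy()
    for i in range(len(dataset.cells)):
        tot = int(counts[i].sum())
        if tot == 0:
            continue
        a, b = _cell_axes(config, int(types[i]))
        r = np.sqrt(rng.uniform(size=tot))
        ang = rng.uniform(0, 2 * np.pi, size=tot)
        px = np.clip(xs[i] + r * a * np.cos(ang), 0, dataset.image_size - 1e-3)
        py = np.clip(ys[i] + r * b * np.sin(ang), 0, dataset.image_size - 1e-3)
        sx[pos:pos + tot] = px
        sy[pos:pos + tot] = py
        sg[pos:pos + tot] = np.repeat(np.arange(config.n_genes), counts[i])
        sc[pos:pos + tot] = dataset.cells["cell"].iloc[i]
        pos += tot

    dataset.spots = pd.DataFrame({"x": sx, "y": sy, "gene": sg, "cell": sc})
    dataset.counts = counts
    dataset.ingested_cell_totals = counts.sum(axis=1)
    dataset.ingested_gene_totals = counts.sum(axis=0)
    return dataset


def render_stains(dataset: SpatialDataset, config: SynthConfig) -> SpatialDataset:
    """Render nuclear (blurred ellipse) and membrane (ring, optionally
    polarized) channels with additive Gaussian noise."""
    rng = np.random.default_rng([config.seed, _STAGE_STAINS])
    size = dataset.image_size
    img = np.zeros((2, size, size), dtype=np.float32)
    yy_full, xx_full = np.mgrid[0:size, 0:size]

    for _, row in dataset.cells.iterrows():
        t = int(row["type"])
        m = config.morphology[t]
        a_cell, b_cell = _cell_axes(config, t)
        a_nuc = m.nucleus_radius
        b_nuc = a_nuc * np.sqrt(max(1.0 - m.eccentricity ** 2, 0.05))
        ext = int(np.ceil(a_cell + m.membrane_width)) + 2
        x0 = max(int(row["x"]) - ext, 0)
        x1 = min(int(row["x"]) + ext + 1, size)
        y0 = max(int(row["y"]) - ext, 0)
        y1 = min(int(row["y"]) + ext + 1, size)
        xx = xx_full[y0:y1, x0:x1] - row["x"]
        yy = yy_full[y0:y1, x0:x1] - row["y"]
        # nuclear ellipse
        rn = (xx / a_nuc) ** 2 + (yy / b_nuc) ** 2
        img[0, y0:y1, x0:x1] += m.nucleus_intensity * (rn <= 1.0)
        # membrane ring at the cell boundary
        rc = np.sqrt((xx / a_cell) ** 2 + (yy / b_cell) ** 2)
        w_norm = m.membrane_width / a_cell
        ring = (rc >= 1.0 - w_norm) & (rc <= 1.0)
        if m.polarized:
            angle = np.arctan2(yy, xx)
            ring_i = ring * (0.5 + 0.5 * np.cos(angle))
        else:
            ring_i = ring.astype(np.float32)
        img[1, y0:y1, x0:x1] += m.membrane_intensity * ring_i

    for ch in range(2):
        img[ch] = gaussian_filter(img[ch], sigma=config.blur_sigma)
    if config.noise_level > 0:
        img += rng.normal(0.0, config.noise_level, size=img.shape).astype(np.float32)
    np.maximum(img, 0.0, out=img)
    dataset.stains = img
    dataset._scaled_stains = None
    return dataset


def generate_dataset(config: SynthConfig) -> SpatialDataset:
    """Run all three stages and verify the core consistency invariant."""
    ds = simulate_cells(config)
    ds = simulate_transcripts(ds, config)
    ds = render_stains(ds, config)
    ds.check_consistency()
    return ds


# ---------------------------------------------------------------------------
# disk round-trip in the real-data input formats, so synthetic and real modes
# share one ingestion path

def write_dataset(ds: SpatialDataset, out_dir: str | Path,
                  config: SynthConfig | None = None) -> None:
    import tifffile
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.cells.drop(columns=["label"]).to_csv(out / "cells.csv", index=False)
    ds.cells[["cell", "label"]].to_csv(out / "labels.csv", index=False)
    if ds.spots is not None:
        ds.spots.to_csv(out / "spots.csv", index=False)
    if ds.counts is not None:
        mmwrite(str(out / "counts.mtx"), coo_matrix(ds.counts))
        (out / "genes.txt").write_text("\n".join(ds.genes) + "\n")
        (out / "cell_index.txt").write_text(
            "\n".join(str(c) for c in ds.cells["cell"]) + "\n")
    if ds.stains is not None:
        tifffile.imwrite(out / "stains.tif", ds.stains)
    manifest = {
        "image_size": ds.image_size,
        "distributions_are_standins": True,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def load_dataset(in_dir: str | Path) -> SpatialDataset:
    import tifffile
    from scipy.io import mmread

    src = Path(in_dir)
    cells = pd.read_csv(src / "cells.csv")
    labels = pd.read_csv(src / "labels.csv")
    cells = cells.merge(labels, on="cell", how="left")
    manifest = json.loads((src / "manifest.json").read_text())
    ds = SpatialDataset(cells=cells, image_size=manifest["image_size"])
    if (src / "spots.csv").exists():
        ds.spots = pd.read_csv(src / "spots.csv")
    if (src / "counts.mtx").exists():
        ds.counts = np.asarray(mmread(str(src / "counts.mtx")).todense()).astype(np.int64)
        ds.genes = (src / "genes.txt").read_text().splitlines()
        ds.ingested_cell_totals = ds.counts.sum(axis=1)
        ds.ingested_gene_totals = ds.counts.sum(axis=0)
    if (src / "stains.tif").exists():
        ds.stains = tifffile.imread(src / "stains.tif").astype(np.float32)
    return ds
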