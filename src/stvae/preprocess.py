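"""Dataset filtering, count normalisation, spot expansion, crop extraction,
rotation augmentation and gene-subset selection.

Filtering thresholds follow a strict-inequality reading: cells *smaller than*
the area threshold or with *fewer than* the transcript threshold are removed,
so boundary values are retained. Cell- and gene-total filters are evaluated on
the raw totals frozen at ingestion, which makes the two filters commute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SpatialDataset

__all__ = [
    "CountMatrixView",
    "MultiPlaneCrop",
    "StainCrop",
    "GeneSubset",
    "filter_cells",
    "drop_unlabeled",
    "normalize_counts",
    "filter_genes_by_total",
    "expand_spots",
    "build_multiplane_crop",
    "extract_stain_crop",
    "random_orthogonal_rotation",
    "select_gene_subset",
]


@dataclass
class CountMatrixView:
    """A cells x genes matrix with an explicit normalisation state.

    Legal state transitions: raw -> median-normalized -> log1p.
    """

    values: np.ndarray
    state: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.state == "raw" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("raw counts must be integer-valued")

    def median_normalize(self) -> "CountMatrixView":
        """Scale each cell so its total equals the median total across cells."""
        if self.state != "raw":
            raise ValueError(f"median_normalize requires raw state, got {self.state}")
        totals = self.values.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(f"cell(s) {zero.tolist()} have zero total count")
        med = np.median(totals)
        scaled = self.values * (med / totals)[:, None]
        return CountMatrixView(scaled.astype(np.float64), state="median-normalized")

    def log1p(self) -> "CountMatrixView":
        if self.state != "median-normalized":
            raise ValueError(f"log1p requires median-normalized state, got {self.state}")
        return CountMatrixView(np.log1p(self.values), state="log1p")


def normalize_counts(counts: CountMatrixView) -> CountMatrixView:
    """Median library-size normalisation followed by log1p."""
    return counts.median_normalize().log1p()


@dataclass
class MultiPlaneCrop:
    """Per-cell G x H x W binary tensor of expanded spots."""

    tensor: np.ndarray
    gene_index_map: list[int]
    cell_id: int
    box: tuple[int, int, int, int]   # (x0, y0, x1, y1), half-open

    def __post_init__(self):
        u = np.unique(self.tensor)
        if not np.all(np.isin(u, [0, 1])):
            raise ValueError("multi-plane crop must be binary")


@dataclass
class StainCrop:
    """2 x H x W float crop; channel order (nuclear, membrane)."""

    tensor: np.ndarray
    cell_id: int
    box: tuple[int, int, int, int]


@dataclass
class GeneSubset:
    method: str
    genes: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("gene subset is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene subset indices must be unique")


# ---------------------------------------------------------------------------
# filtering

def _subset_cells(ds: SpatialDataset, keep_mask: np.ndarray) -> SpatialDataset:
    cells = ds.cells.loc[keep_mask].reset_index(drop=True)
    keep_ids = set(cells["cell"].tolist())
    spots = None
    if ds.spots is not None:
        spots = ds.spots[ds.spots["cell"].isin(keep_ids)].reset_index(drop=True)
    counts = ds.counts[keep_mask] if ds.counts is not None else None
    return SpatialDataset(
        cells=cells, genes=list(ds.genes), spots=spots, counts=counts,
        stains=ds.stains, image_size=ds.image_size,
        ingested_cell_totals=(ds.ingested_cell_totals[keep_mask]
                              if ds.ingested_cell_totals is not None else None),
        ingested_gene_totals=ds.ingested_gene_totals,
    )


def filter_cells(ds: SpatialDataset, min_area_px: float = 50,
                 min_transcripts: int = 10) -> SpatialDataset:
    """Remove cells smaller than ``min_area_px`` or with fewer than
    ``min_transcripts`` assigned transcripts (strict; boundary kept)."""
    if ds.ingested_cell_totals is not None:
        totals = ds.ingested_cell_totals
    elif ds.counts is not None:
        totals = ds.counts.sum(axis=1)
    elif ds.spots is not None:
        vc = ds.spots["cell"].value_counts()
        totals = ds.cells["cell"].map(vc).fillna(0).to_numpy()
    else:
        raise ValueError("cannot compute per-cell totals: no counts or spots")
    areas = ds.cells["area"].to_numpy()
    keep = (areas >= min_area_px) & (totals >= min_transcripts)
    if not keep.any():
        warnings.warn("all cells removed by filter_cells")
    return _subset_cells(ds, keep)


def drop_unlabeled(ds: SpatialDataset) -> SpatialDataset:
    if "label" not in ds.cells.columns:
        raise ValueError("dataset has no label column")
    keep = ds.cells["label"].notna().to_numpy()
    if not keep.any():
        warnings.warn("all cells are unlabeled; result is empty")
    return _subset_cells(ds, keep)


def filter_genes_by_total(ds: SpatialDataset, min_total: int = 100) -> SpatialDataset:
    """Discard genes with fewer than ``min_total`` transcripts across the
    tissue (raw ingested totals; strict, boundary kept)."""
    if ds.ingested_gene_totals is not None:
        totals = ds.ingested_gene_totals
    elif ds.counts is not None:
        totals = ds.counts.sum(axis=0)
    else:
        raise ValueError("no counts available")
    keep = np.flatnonzero(totals >= min_total)
    remap = -np.ones(len(ds.genes), dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    spots = None
    if ds.spots is not None:
        spots = ds.spots[np.isin(ds.spots["gene"].to_numpy(), keep)].copy()
        spots["gene"] = remap[spots["gene"].to_numpy()]
        spots = spots.reset_index(drop=True)
    return SpatialDataset(
        cells=ds.cells.copy(), genes=[ds.genes[i] for i in keep], spots=spots,
        counts=ds.counts[:, keep] if ds.counts is not None else None,
        stains=ds.stains, image_size=ds.image_size,
        ingested_cell_totals=ds.ingested_cell_totals,
        ingested_gene_totals=(ds.ingested_gene_totals[keep]
                              if ds.ingested_gene_totals is not None else None),
    )


# ---------------------------------------------------------------------------
# spot expansion and crops

def _kernel_offsets(p: int) -> tuple[range, range]:
    """Row/col offsets of the (p+2) x (p+2) expansion kernel.

    Odd kernels are centred; even kernels anchor the extra row/column toward
    increasing indices: a spot at (r, c) covers r - (k/2 - 1) .. r + k/2.
    """
    if p < 0:
        raise ValueError("padding p must be >= 0")
    k = p + 2
    if k % 2 == 1:
        h = (k - 1) // 2
        return range(-h, h + 1), range(-h, h + 1)
    h = k // 2
    return range(-(h - 1), h + 1), range(-(h - 1), h + 1)


def expand_spots(plane: np.ndarray, padding_p: int) -> np.ndarray:
    """Dilate single-pixel spots with a (p+2) x (p+2) structuring element;
    overlaps merge by logical OR."""
    plane = np.asarray(plane).astype(bool)
    out = np.zeros_like(plane)
    H, W = plane.shape
    rows, cols = _kernel_offsets(padding_p)
    for dr in rows:
        for dc in cols:
            src_r0, src_r1 = max(0, -dr), min(H, H - dr)
            src_c0, src_c1 = max(0, -dc), min(W, W - dc)
            out[src_r0 + dr:src_r1 + dr, src_c0 + dc:src_c1 + dc] |= \
                plane[src_r0:src_r1, src_c0:src_c1]
    return out.astype(np.uint8)


def _crop_window(ds: SpatialDataset, cell_id: int, crop_size: int) -> tuple[int, int, int, int]:
    row = ds.cells.iloc[ds.cell_row(cell_id)]
    cx, cy = int(np.floor(row["x"])), int(np.floor(row["y"]))
    half = crop_size // 2
    return cx - half, cy - half, cx - half + crop_size, cy - half + crop_size


def build_multiplane_crop(ds: SpatialDataset, cell_id: int, crop_size: int,
                          padding_p: int, gene_set: list[int],
                          border_policy: str = "zero-pad") -> MultiPlaneCrop:
    """Rasterise and expand the spots of each gene falling inside the cell's
    bounding-box window (from any cell: bounding-box, not mask, semantics)."""
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    x0, y0, x1, y1 = _crop_window(ds, cell_id, crop_size)
    if border_policy == "strict" and (x0 < 0 or y0 < 0 or
                                      x1 > ds.image_size or y1 > ds.image_size):
        raise ValueError(f"crop for cell {cell_id} extends past the image")
    tensor = np.zeros((len(gene_set), crop_size, crop_size), dtype=np.uint8)
    if ds.spots is not None and len(ds.spots):
        sx = ds.spots["x"].to_numpy()
        sy = ds.spots["y"].to_numpy()
        sg = ds.spots["gene"].to_numpy()
        inside = (sx >= x0) & (sx < x1) & (sy >= y0) & (sy < y1)
        for pi, g in enumerate(gene_set):
            sel = inside & (sg == g)
            if not sel.any():
                continue
            plane = np.zeros((crop_size, crop_size), dtype=bool)
            rr = np.floor(sy[sel]).astype(int) - y0
            cc = np.floor(sx[sel]).astype(int) - x0
            plane[rr, cc] = True
            tensor[pi] = expand_spots(plane, padding_p)
    return MultiPlaneCrop(tensor=tensor, gene_index_map=list(gene_set),
                          cell_id=cell_id, box=(x0, y0, x1, y1))


def extract_stain_crop(ds: SpatialDataset, cell_id: int, crop_size: int,
                       border_policy: str = "zero-pad") -> StainCrop:
    """Window the per-channel [0,1]-scaled stain stack around the cell
    centroid; out-of-image pixels are zero under the zero-pad policy."""
    img = ds.scaled_stains()
    x0, y0, x1, y1 = _crop_window(ds, cell_id, crop_size)
    if border_policy == "strict" and (x0 < 0 or y0 < 0 or
                                      x1 > ds.image_size or y1 > ds.image_size):
        raise ValueError(f"crop for cell {cell_id} extends past the image")
    out = np.zeros((2, crop_size, crop_size), dtype=np.float32)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x1, ds.image_size), min(y1, ds.image_size)
    if sx1 > sx0 and sy1 > sy0:
        out[:, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = img[:, sy0:sy1, sx0:sx1]
    return StainCrop(tensor=out, cell_id=cell_id, box=(x0, y0, x1, y1))


def random_orthogonal_rotation(tc: np.ndarray, stain: np.ndarray | None,
                               rng: np.random.Generator
                               ) -> tuple[np.ndarray, np.ndarray | None, int]:
    """One rotation drawn uniformly from {0, 90, 180, 270} degrees (counter-
    clockwise; (r, c) -> (W-1-c, r) for 90), applied identically to all planes
    of both modalities. Returns the rotated tensors and the draw."""
    if tc.shape[-1] != tc.shape[-2]:
        raise ValueError("rotation requires square crops")
    if stain is not None and stain.shape[-1] != stain.shape[-2]:
        raise ValueError("rotation requires square crops")
    k = int(rng.integers(4))
    tc_r = np.rot90(tc, k, axes=(-2, -1))
    st_r = np.rot90(stain, k, axes=(-2, -1)) if stain is not None else None
    return tc_r, st_r, k


# ---------------------------------------------------------------------------
# gene subsets

def select_gene_subset(counts: CountMatrixView, labels: np.ndarray | None,
                       method: str, n_pcs: int = 15, top_per_pc: int = 3,
                       n_random: int = 19,
                       rng: np.random.Generator | None = None) -> GeneSubset:
    """Three reduced-gene strategies: PCA top-loading union, top marker per
    label by one-vs-rest Wilcoxon rank-sum, or a seeded random draw."""
    from scipy.stats import ranksums

    if counts.state != "log1p":
        raise ValueError("select_gene_subset expects normalized log1p counts")
    X = counts.values
    n_genes = X.shape[1]
    if method == "random":
        if rng is None:
            raise ValueError("random selection requires an rng")
        genes = sorted(rng.choice(n_genes, size=n_random, replace=False).tolist())
        return GeneSubset("random", genes, {"n_random": n_random})
    if method == "pca":
        from sklearn.decomposition import PCA

        sd = X.std(axis=0)
        Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        n_comp = min(n_pcs, min(Z.shape) - 1)
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(Z)
        chosen: list[int] = []
        for comp in pca.components_:
            # ties in |loading| broken by ascending gene index
            order = np.lexsort((np.arange(n_genes), -np.abs(comp)))
            chosen.extend(order[:top_per_pc].tolist())
        genes = sorted(set(chosen))
        return GeneSubset("pca", genes, {"n_pcs": n_comp, "top_per_pc": top_per_pc})
    if method == "gt":
        if labels is None:
            raise ValueError("gt selection requires labels")
        labels = np.asarray(labels)
        chosen = []
        for lab in pd.unique(labels):
            mask = labels == lab
            stats = np.zeros(n_genes)
            for g in range(n_genes):
                stats[g] = ranksums(X[mask, g], X[~mask, g]).statistic
            order = np.lexsort((np.arange(n_genes), -stats))
            chosen.append(int(order[0]))
        genes = sorted(set(chosen))
        return GeneSubset("gt", genes, {"labels": [str(l) for l in pd.unique(labels)]})
    raise ValueError(f"unknown method {method!r}")
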