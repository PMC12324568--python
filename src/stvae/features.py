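"""Classical morphological profiling of dual-channel stain crops.

This is the hand-crafted comparator to the learned embeddings: per-channel
intensity summaries, radial intensity distribution, gray-level co-occurrence
texture and a granularity spectrum, mirroring the measurement families of
standard image-profiling pipelines (no claim of numerical parity with any
external tool — the role, not the numbers, is reproduced; definitions are
pinned in docs/methods.md). Followed by the usual feature-selection chain:
drop-NA, blocklist, variance threshold, correlation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix
from skimage.morphology import disk, opening

__all__ = ["FeatureTable", "extract_classical_features", "select_features"]

_CHANNELS = ("nuclear", "membrane")
_N_RADIAL_BINS = 4
_GLCM_OFFSETS = (1, 3)
_N_GRANULARITY = 8
_GLCM_LEVELS = 32


@dataclass
class FeatureTable:
    values: pd.DataFrame
    crop_size: int

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")


def _intensity_features(img: np.ndarray) -> dict[str, float]:
    h, w = img.shape
    total = img.sum()
    out = {
        "int_mean": float(img.mean()),
        "int_sd": float(img.std()),
        "int_q25": float(np.quantile(img, 0.25)),
        "int_median": float(np.median(img)),
        "int_q75": float(np.quantile(img, 0.75)),
    }
    # mass displacement: distance between intensity centroid and crop centre
    if total > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        cy = float((yy * img).sum() / total)
        cx = float((xx * img).sum() / total)
        out["mass_displacement"] = float(
            np.hypot(cy - (h - 1) / 2.0, cx - (w - 1) / 2.0))
    else:
        out["mass_displacement"] = 0.0
    return out


def _radial_features(img: np.ndarray) -> dict[str, float]:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    rmax = r.max() + 1e-9
    total = img.sum()
    out = {}
    for b in range(_N_RADIAL_BINS):
        lo, hi = b / _N_RADIAL_BINS * rmax, (b + 1) / _N_RADIAL_BINS * rmax
        mask = (r >= lo) & (r < hi) if b < _N_RADIAL_BINS - 1 else (r >= lo)
        out[f"radial_frac_{b + 1}"] = \
            float(img[mask].sum() / total) if total > 0 else 0.0
    return out


def _texture_features(img: np.ndarray) -> dict[str, float]:
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        q = np.zeros_like(img, dtype=np.uint8)
    else:
        q = np.clip(((img - lo) / (hi - lo) * (_GLCM_LEVELS - 1)), 0,
                    _GLCM_LEVELS - 1).astype(np.uint8)
    angles = (0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    P = graycomatrix(q, distances=_GLCM_OFFSETS, angles=angles,
                     levels=_GLCM_LEVELS, symmetric=True, normed=True)
    i_idx, j_idx = np.mgrid[0:_GLCM_LEVELS, 0:_GLCM_LEVELS]
    out = {}
    for di, d in enumerate(_GLCM_OFFSETS):
        Pd = P[:, :, di, :]                       # (L, L, angles)
        contrast = ((i_idx - j_idx)[..., None] ** 2 * Pd).sum(axis=(0, 1))
        mu_i = (i_idx[..., None] * Pd).sum(axis=(0, 1))
        mu_j = (j_idx[..., None] * Pd).sum(axis=(0, 1))
        sd_i = np.sqrt(((i_idx[..., None] - mu_i) ** 2 * Pd).sum(axis=(0, 1)))
        sd_j = np.sqrt(((j_idx[..., None] - mu_j) ** 2 * Pd).sum(axis=(0, 1)))
        cov = (((i_idx[..., None] - mu_i) * (j_idx[..., None] - mu_j)) * Pd
               ).sum(axis=(0, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(sd_i * sd_j > 0, cov / (sd_i * sd_j), 0.0)
        ent = -(Pd * np.log(Pd + 1e-12)).sum(axis=(0, 1))
        out[f"texture_contrast_d{d}"] = float(contrast.mean())
        out[f"texture_correlation_d{d}"] = float(corr.mean())
        out[f"texture_entropy_d{d}"] = float(ent.mean())
    return out


def _granularity_features(img: np.ndarray) -> dict[str, float]:
    total = img.sum()
    out = {}
    prev = img
    for i in range(1, _N_GRANULARITY + 1):
        opened = opening(img, disk(i))
        removed = float((prev.sum() - opened.sum()) / total) if total > 0 else 0.0
        out[f"granularity_{i}"] = removed
        prev = opened
    return out


def extract_classical_features(stain_crops: np.ndarray,
                               cell_ids: np.ndarray | None = None) -> FeatureTable:
    """Deterministic feature table from an (N, 2, H, W) stack of stain crops."""
    crops = np.asarray(stain_crops, dtype=np.float64)
    if crops.ndim != 4 or crops.shape[1] != 2:
        raise ValueError("expected an (N, 2, H, W) crop stack")
    if crops.shape[2] != crops.shape[3]:
        raise ValueError("crops must be square")
    rows = []
    for i in range(crops.shape[0]):
        row: dict[str, float] = {}
        for ch, name in enumerate(_CHANNELS):
            img = crops[i, ch]
            for fam in (_intensity_features, _radial_features,
                        _texture_features, _granularity_features):
                for k, v in fam(img).items():
                    row[f"{name}_{k}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    if cell_ids is not None:
        df.index = pd.Index(cell_ids, name="cell")
    return FeatureTable(values=df, crop_size=crops.shape[2])


def select_features(table: FeatureTable, var_thresh: float = 1e-10,
                    corr_thresh: float = 0.95,
                    blocklist: list[str] | None = None) -> FeatureTable:
    """NA -> blocklist -> variance -> correlation, in that order.

    The correlation step removes, from each |r| > threshold pair, the feature
    with the larger mean |r| to all remaining features (ties by name order).
    Idempotent by construction.
    """
    df = table.values.copy()
    df = df.dropna(axis=1)
    if blocklist:
        df = df.drop(columns=[c for c in blocklist if c in df.columns])
    variances = df.var(axis=0, ddof=0)
    df = df.loc[:, variances > var_thresh]
    if df.shape[1] == 0:
        raise ValueError("all features dropped by selection")
    corr = df.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    cols = sorted(df.columns)
    dropped: set[str] = set()
    while True:
        active = [c for c in cols if c not in dropped]
        sub = corr.loc[active, active]
        if sub.size == 0 or (sub.values <= corr_thresh).all():
            break
        mean_r = sub.mean(axis=0)
        # worst remaining correlated pair; drop the member with higher mean |r|
        stacked = sub.stack()
        pair = stacked.idxmax()
        a, b = pair
        if abs(mean_r[a] - mean_r[b]) < 1e-15:
            drop = max(a, b)          # tie: drop the later name
        else:
            drop = a if mean_r[a] > mean_r[b] else b
        dropped.add(drop)
    keep = [c for c in df.columns if c not in dropped]
    out = df[keep]
    if out.shape[1] == 0:
        raise ValueError("all features dropped by selection")
    return FeatureTable(values=out, crop_size=table.crop_size)
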