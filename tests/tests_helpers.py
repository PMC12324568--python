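"""Shared toy-data builders for the test suite."""

import numpy as np
import pandas as pd

from stvae.synthetic import SpatialDataset


def toy_dataset(areas, counts, labels=None):
    """Minimal consistent SpatialDataset from per-cell areas and counts."""
    n = len(areas)
    cells = pd.DataFrame({
        "cell": np.arange(n), "x": np.linspace(50, 80, n),
        "y": np.linspace(50, 80, n), "type": np.zeros(n, dtype=int),
        "label": labels if labels is not None else [f"t{i}" for i in range(n)],
        "area": areas,
    })
    counts = np.asarray(counts)
    rows = []
    for i in range(n):
        for g in range(counts.shape[1]):
            rows.extend({"x": cells["x"][i], "y": cells["y"][i],
                         "gene": g, "cell": i}
                        for _ in range(int(counts[i, g])))
    ds = SpatialDataset(cells=cells,
                        genes=[f"g{j}" for j in range(counts.shape[1])],
                        spots=pd.DataFrame(rows, columns=["x", "y", "gene",
                                                          "cell"]),
                        counts=counts, image_size=128)
    ds.ingested_cell_totals = counts.sum(axis=1)
    ds.ingested_gene_totals = counts.sum(axis=0)
    return ds


def dominant_gene_dataset(seed=0, n=100, genes=3, dom_rate=40.0,
                          rare_rate=2.0, radius=8):
    """Grid of identical cells where gene 0 dwarfs the others; exposes the
    reconstruction bias that dynamic gene weighting is meant to correct."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n)))
    xs = np.array([24.0 + (i % side) * 40 for i in range(n)])
    ys = np.array([24.0 + (i // side) * 40 for i in range(n)])
    cells = pd.DataFrame({"cell": range(n), "x": xs, "y": ys, "type": 0,
                          "label": "a", "area": np.pi * radius ** 2})
    counts = np.zeros((n, genes), dtype=np.int64)
    counts[:, 0] = rng.poisson(dom_rate, n)
    counts[:, 1:] = rng.poisson(rare_rate, (n, genes - 1))
    rows = []
    for i in range(n):
        for g in range(genes):
            k = counts[i, g]
            r = np.sqrt(rng.uniform(size=k)) * radius
            a = rng.uniform(0, 2 * np.pi, k)
            rows.extend({"x": x, "y": y, "gene": g, "cell": i}
                        for x, y in zip(xs[i] + r * np.cos(a),
                                        ys[i] + r * np.sin(a)))
    size = 48 + side * 40
    ds = SpatialDataset(cells=cells, genes=[f"g{i}" for i in range(genes)],
                        spots=pd.DataFrame(rows, columns=["x", "y", "gene",
                                                          "cell"]),
                        counts=counts, image_size=size)
    ds.ingested_cell_totals = counts.sum(axis=1)
    ds.ingested_gene_totals = counts.sum(axis=0)
    return ds
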