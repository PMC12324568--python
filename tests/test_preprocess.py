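"""Filtering, normalisation, spot expansion, crops, rotation, gene subsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stvae.preprocess import (CountMatrixView, GeneSubset, build_multiplane_crop,
                              drop_unlabeled, expand_spots, extract_stain_crop,
                              filter_cells, filter_genes_by_total,
                              normalize_counts, random_orthogonal_rotation,
                              select_gene_subset)
from stvae.synthetic import SpatialDataset
from tests_helpers import toy_dataset as _toy_dataset


class TestFilters:
    def test_area_boundary_is_strict(self):
        ds = _toy_dataset([49, 50, 51], np.full((3, 2), 10))
        out = filter_cells(ds)
        assert out.cells["area"].tolist() == [50, 51]

    def test_transcript_boundary_is_strict(self):
        ds = _toy_dataset([100, 100, 100], [[4, 5], [5, 5], [6, 6]])
        out = filter_cells(ds)
        assert out.ingested_cell_totals.tolist() == [10, 12]

    def test_empty_dataset_passes_through(self):
        ds = _toy_dataset([10], [[1, 1]])
        with pytest.warns(UserWarning):
            out = filter_cells(ds, min_area_px=1000)
        assert out.n_cells == 0

    def test_gene_total_boundary_is_strict(self):
        counts = np.array([[99, 100, 101]])
        ds = _toy_dataset([100], counts)
        out = filter_genes_by_total(ds, min_total=100)
        assert out.genes == ["g1", "g2"]
        assert out.counts.tolist() == [[100, 101]]

    def test_gene_filter_remaps_spot_indices(self):
        counts = np.array([[99, 100, 101]])
        ds = _toy_dataset([100], counts)
        out = filter_genes_by_total(ds, min_total=100)
        assert set(out.spots["gene"]) == {0, 1}
        out_counts = np.zeros_like(out.counts)
        for g in out.spots["gene"]:
            out_counts[0, g] += 1
        assert np.array_equal(out_counts, out.counts)

    def test_min_total_zero_is_identity(self):
        ds = _toy_dataset([100, 100], [[1, 2], [3, 4]])
        out = filter_genes_by_total(ds, min_total=0)
        assert out.genes == ds.genes and np.array_equal(out.counts, ds.counts)

    def test_filters_commute(self, small_dataset):
        ds, _ = small_dataset
        a = filter_genes_by_total(filter_cells(ds, 50, 3), 20)
        b = filter_cells(filter_genes_by_total(ds, 20), 50, 3)
        assert a.cells["cell"].tolist() == b.cells["cell"].tolist()
        assert a.genes == b.genes
        assert np.array_equal(a.counts, b.counts)

    def test_drop_unlabeled(self):
        ds = _toy_dataset([100] * 4, np.full((4, 2), 5),
                          labels=["a", None, "b", None])
        out = drop_unlabeled(ds)
        assert out.cells["label"].tolist() == ["a", "b"]

    def test_drop_unlabeled_without_column_raises(self):
        ds = _toy_dataset([100], [[1, 1]])
        ds.cells = ds.cells.drop(columns=["label"])
        with pytest.raises(ValueError, match="label"):
            drop_unlabeled(ds)


class TestNormalization:
    def test_scaling_matches_median_exactly(self):
        counts = CountMatrixView(np.array([[10, 0], [10, 10], [20, 10]]))
        mid = counts.median_normalize()
        assert mid.state == "median-normalized"
        totals = mid.values.sum(axis=1)
        assert np.allclose(totals, 20.0)
        # worked example: per-cell totals [10, 20, 30] -> scale [2, 1, 2/3]
        assert np.allclose(mid.values[0], [20, 0])
        assert np.allclose(mid.values[2], [40 / 3, 20 / 3])

    def test_zeros_stay_zero_through_log1p(self):
        out = normalize_counts(CountMatrixView(np.array([[5, 0], [5, 5]])))
        assert out.state == "log1p"
        assert out.values[0, 1] == 0.0

    def test_identical_totals_scaling_is_identity(self):
        raw = np.array([[3, 7], [5, 5]])
        mid = CountMatrixView(raw).median_normalize()
        assert np.allclose(mid.values, raw)

    def test_zero_total_cell_raises_with_cell_named(self):
        with pytest.raises(ValueError, match="1"):
            CountMatrixView(np.array([[5, 5], [0, 0]])).median_normalize()

    def test_median_conserved(self, small_dataset):
        ds, _ = small_dataset
        keep = ds.counts.sum(axis=1) > 0
        raw = ds.counts[keep]
        mid = CountMatrixView(raw).median_normalize()
        assert np.isclose(np.median(mid.values.sum(axis=1)),
                          np.median(raw.sum(axis=1)))

    def test_state_transitions_enforced(self):
        v = CountMatrixView(np.array([[1, 2]]))
        with pytest.raises(ValueError):
            v.log1p()                      # raw -> log1p not allowed
        with pytest.raises(ValueError):
            v.median_normalize().median_normalize()


class TestExpandSpots:
    def test_p3_gives_5x5_footprint(self):
        plane = np.zeros((21, 21)); plane[10, 10] = 1
        out = expand_spots(plane, 3)
        rows, cols = np.nonzero(out)
        assert rows.min() == 8 and rows.max() == 12
        assert cols.min() == 8 and cols.max() == 12
        assert out.sum() == 25

    def test_p4_even_kernel_anchors_toward_increasing_indices(self):
        plane = np.zeros((21, 21)); plane[10, 10] = 1
        out = expand_spots(plane, 4)
        rows, cols = np.nonzero(out)
        assert rows.min() == 8 and rows.max() == 13   # r-(k/2-1) .. r+k/2
        assert out.sum() == 36

    def test_empty_plane_stays_empty(self):
        assert expand_spots(np.zeros((8, 8)), 2).sum() == 0

    def test_negative_padding_rejected(self):
        with pytest.raises(ValueError):
            expand_spots(np.zeros((4, 4)), -1)

    @settings(deadline=None, max_examples=25)
    @given(p=st.integers(0, 4), n_spots=st.integers(1, 6),
           seed=st.integers(0, 100))
    def test_foreground_bounds(self, p, n_spots, seed):
        """Output foreground >= spot count, and equals |kernel| * spots for
        well-separated interior spots."""
        rng = np.random.default_rng(seed)
        plane = np.zeros((60, 60))
        k = p + 2
        # place spots on a coarse grid so footprints never overlap
        cells_side = 60 // (2 * k)
        picks = rng.choice(cells_side * cells_side,
                           size=min(n_spots, cells_side * cells_side),
                           replace=False)
        for idx in picks:
            r = (idx // cells_side) * 2 * k + k
            c = (idx % cells_side) * 2 * k + k
            plane[r, c] = 1
        out = expand_spots(plane, p)
        assert out.sum() == plane.sum() * k * k


class TestCrops:
    def test_empty_window_gives_zero_tensor(self):
        cells = pd.DataFrame({"cell": [0], "x": [50.0], "y": [50.0],
                              "type": [0], "label": ["a"], "area": [100.0]})
        spots = pd.DataFrame({"x": [100.0], "y": [100.0], "gene": [0],
                              "cell": [0]})        # far outside the window
        ds = SpatialDataset(cells=cells, genes=["g0", "g1"], spots=spots,
                            counts=np.array([[1, 0]]), image_size=128)
        crop = build_multiplane_crop(ds, 0, 16, 2, [0, 1])
        assert crop.tensor.shape == (2, 16, 16)
        assert crop.tensor.sum() == 0

    def test_single_spot_lands_in_its_gene_plane(self):
        cells = pd.DataFrame({"cell": [0], "x": [50.0], "y": [50.0],
                              "type": [0], "label": ["a"], "area": [100.0]})
        spots = pd.DataFrame({"x": [50.0], "y": [50.0], "gene": [1], "cell": [0]})
        ds = SpatialDataset(cells=cells, genes=["g0", "g1"], spots=spots,
                            counts=np.array([[0, 1]]), image_size=128)
        crop = build_multiplane_crop(ds, 0, 16, 0, [0, 1])
        assert crop.tensor[0].sum() == 0
        assert crop.tensor[1].sum() == 4          # p=0 -> 2x2 kernel
        assert crop.tensor[1, 8, 8] == 1

    def test_neighbor_spots_included_bounding_box_semantics(self):
        cells = pd.DataFrame({"cell": [0, 1], "x": [50.0, 54.0], "y": [50.0, 50.0],
                              "type": [0, 0], "label": ["a", "a"],
                              "area": [100.0, 100.0]})
        spots = pd.DataFrame({"x": [50.0, 54.0], "y": [50.0, 50.0],
                              "gene": [0, 0], "cell": [0, 1]})
        ds = SpatialDataset(cells=cells, genes=["g0"], spots=spots,
                            counts=np.array([[1], [1]]), image_size=128)
        crop = build_multiplane_crop(ds, 0, 16, 0, [0])
        assert crop.tensor[0, 8, 8] == 1 and crop.tensor[0, 8, 12] == 1

    def test_stain_crop_matches_scaled_window(self, small_dataset):
        ds, _ = small_dataset
        cell = int(ds.cells["cell"].iloc[0])
        crop = extract_stain_crop(ds, cell, 32)
        x0, y0, x1, y1 = crop.box
        expected = ds.scaled_stains()[:, y0:y1, x0:x1]
        assert np.array_equal(crop.tensor, expected)
        assert crop.tensor.min() >= 0 and crop.tensor.max() <= 1

    def test_small_crop_is_center_of_large_crop(self, small_dataset):
        ds, _ = small_dataset
        cell = int(ds.cells["cell"].iloc[3])
        big = extract_stain_crop(ds, cell, 48).tensor
        small = extract_stain_crop(ds, cell, 16).tensor
        assert np.array_equal(small, big[:, 16:32, 16:32])

    def test_border_cell_zero_padded(self):
        cells = pd.DataFrame({"cell": [0], "x": [2.0], "y": [2.0], "type": [0],
                              "label": ["a"], "area": [50.0]})
        ds = SpatialDataset(cells=cells, genes=["g0"], spots=pd.DataFrame(
            columns=["x", "y", "gene", "cell"]), counts=np.array([[0]]),
            stains=np.ones((2, 64, 64), dtype=np.float32), image_size=64)
        crop = extract_stain_crop(ds, 0, 16)
        assert crop.tensor[:, 0, 0].sum() == 0      # out-of-image corner
        with pytest.raises(ValueError, match="past the image"):
            extract_stain_crop(ds, 0, 16, border_policy="strict")

    def test_translation_consistency(self, small_dataset):
        ds, _ = small_dataset
        cell = int(ds.cells["cell"].iloc[5])
        base = build_multiplane_crop(ds, cell, 32, 2, list(range(ds.n_genes)))
        shifted = SpatialDataset(
            cells=ds.cells.assign(x=ds.cells["x"] + 7, y=ds.cells["y"] + 3),
            genes=ds.genes,
            spots=ds.spots.assign(x=ds.spots["x"] + 7, y=ds.spots["y"] + 3),
            counts=ds.counts, image_size=ds.image_size + 16)
        moved = build_multiplane_crop(shifted, cell, 32, 2, list(range(ds.n_genes)))
        assert np.array_equal(base.tensor, moved.tensor)


class TestRotation:
    def test_rotation_convention_90_ccw(self, rng):
        pattern = np.zeros((1, 3, 3)); pattern[0, 0, 2] = 1   # (r=0, c=2)
        class FixedRng:
            def integers(self, n): return 1
        tc, _, k = random_orthogonal_rotation(pattern, None, FixedRng())
        assert k == 1
        # (r, c) -> (W-1-c, r): (0, 2) -> (0, 0)
        assert tc[0, 0, 0] == 1 and tc.sum() == 1

    def test_four_rotations_identity(self, rng):
        x = rng.random((2, 8, 8))
        y = x.copy()
        class FixedRng:
            def integers(self, n): return 1
        for _ in range(4):
            y, _, _ = random_orthogonal_rotation(y, None, FixedRng())
        assert np.allclose(x, y)

    def test_same_rotation_applied_to_both_modalities(self, rng):
        tc = rng.random((3, 8, 8))
        st = rng.random((2, 8, 8))
        tc_r, st_r, k = random_orthogonal_rotation(tc, st, rng)
        assert np.allclose(tc_r, np.rot90(tc, k, axes=(-2, -1)))
        assert np.allclose(st_r, np.rot90(st, k, axes=(-2, -1)))

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            random_orthogonal_rotation(np.zeros((1, 4, 6)), None, rng)


class TestGeneSubsets:
    def _log_counts(self, values):
        return normalize_counts(CountMatrixView(np.asarray(values)))

    def test_random_reproducible_and_unique(self):
        counts = self._log_counts(np.random.default_rng(1).poisson(
            3, size=(40, 30)) + 1)
        a = select_gene_subset(counts, None, "random", n_random=19,
                               rng=np.random.default_rng(5))
        b = select_gene_subset(counts, None, "random", n_random=19,
                               rng=np.random.default_rng(5))
        assert a.genes == b.genes and len(set(a.genes)) == 19

    def test_gt_recovers_planted_markers(self):
        rng = np.random.default_rng(2)
        labels = np.repeat(["a", "b", "c"], 40)
        base = rng.poisson(2, size=(120, 9)) + 1
        for i, lab in enumerate(("a", "b", "c")):
            base[labels == lab, i * 3] += 25      # marker genes 0, 3, 6
        counts = self._log_counts(base)
        sub = select_gene_subset(counts, labels, "gt")
        assert sorted(sub.genes) == [0, 3, 6]

    def test_pca_rank1_collapses_to_three_genes(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=(60, 1))
        v = np.zeros((1, 10)); v[0, [2, 5, 7]] = (3.0, 2.5, 2.0)
        X = u @ v + rng.normal(scale=1e-3, size=(60, 10))
        X = np.round(np.abs(X) * 10).astype(int) + 1
        counts = self._log_counts(X)
        sub = select_gene_subset(counts, None, "pca", n_pcs=5, top_per_pc=3)
        # every PC beyond the first is noise, but the dominant direction's
        # three loading genes must be selected
        assert {2, 5, 7} <= set(sub.genes)

    def test_gt_without_labels_raises(self):
        counts = self._log_counts(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError):
            select_gene_subset(counts, None, "gt")

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            GeneSubset("random", [])
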