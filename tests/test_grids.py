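"""Raster model, covariate operators and file I/O."""

import itertools

import numpy as np
import pytest

from sdmtransfer.grids import (CategoricalGrid, CovariateStack, Grid,
                               RegionPartition, admissible_variable_sets,
                               aggregate_proportion, correlation_matrix,
                               distance_to_class, map_correlation,
                               read_ascii_grid, read_geotiff,
                               write_ascii_grid, write_geotiff)


def grid_of(values, **kw):
    return Grid(np.asarray(values, dtype=float), **kw)


class TestGridGeometry:
    def test_half_open_cell_assignment(self):
        g = grid_of(np.zeros((4, 5)), cell_size=2.0, origin=(10.0, 20.0))
        row, col = g.cell_of(np.array([10.0, 11.9, 12.0, 9.9]),
                             np.array([20.0, 21.9, 22.0, 20.5]))
        assert col.tolist() == [0, 0, 1, -1]   # left edge in, right edge next
        assert row.tolist() == [0, 0, 1, -1]

    def test_extract_respects_nodata(self):
        vals = np.arange(6, dtype=float).reshape(2, 3)
        mask = np.ones((2, 3), bool)
        mask[0, 1] = False
        g = Grid(vals, mask)
        out = g.extract(np.array([0.5, 1.5]), np.array([0.5, 0.5]))
        assert out[0] == 0.0 and np.isnan(out[1])

    def test_stack_requires_alignment(self):
        a = grid_of(np.zeros((3, 3)))
        b = grid_of(np.zeros((3, 4)))
        with pytest.raises(Exception):
            CovariateStack({"a": a, "b": b})


class TestAggregateProportion:
    def test_saturated_and_empty_blocks(self):
        fine = CategoricalGrid(np.full((10, 10), 1))
        out = aggregate_proportion(fine, {1}, 10)
        assert out.shape == (1, 1) and out.values[0, 0] == 1.0
        assert aggregate_proportion(fine, {2}, 10).values[0, 0] == 0.0

    def test_checkerboard_half(self):
        v = np.indices((8, 8)).sum(axis=0) % 2
        out = aggregate_proportion(CategoricalGrid(v), {1}, 4)
        assert np.all(out.values == 0.5)

    def test_partition_sums_to_one_and_trailing_dropped(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 3, size=(23, 17))
        fine = CategoricalGrid(v)
        parts = [aggregate_proportion(fine, {c}, 5) for c in (0, 1, 2)]
        assert parts[0].shape == (4, 3)          # floor(23/5), floor(17/5)
        total = sum(p.values for p in parts)
        assert np.allclose(total, 1.0)
        assert parts[0].cell_size == 5.0

    def test_empty_target_classes_error(self):
        with pytest.raises(ValueError):
            aggregate_proportion(CategoricalGrid(np.zeros((4, 4), int)),
                                 set(), 2)

    def test_all_nodata_block_is_nodata(self):
        mask = np.ones((4, 4), bool)
        mask[:2, :2] = False
        out = aggregate_proportion(
            CategoricalGrid(np.ones((4, 4), int), mask), {1}, 2)
        assert not out.valid_mask[0, 0] and out.valid_mask[1, 1]


class TestDistanceToClass:
    def test_target_and_neighbor(self):
        m = np.zeros((5, 5))
        m[2, 2] = 1
        d = distance_to_class(grid_of(m))
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == 1.0
        assert np.isclose(d.values[3, 3], np.sqrt(2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = (rng.random((30, 30)) < 0.05).astype(float)
            if not m.any():
                m[0, 0] = 1
            d = distance_to_class(grid_of(m, cell_size=2.0))
            targets = np.argwhere(m == 1)
            rr, cc = np.indices(m.shape)
            brute = np.min(
                np.sqrt((rr[..., None] - targets[:, 0]) ** 2
                        + (cc[..., None] - targets[:, 1]) ** 2), axis=-1) * 2.0
            assert np.allclose(d.values, brute)

    def test_no_target_cells_error(self):
        with pytest.raises(ValueError):
            distance_to_class(grid_of(np.zeros((4, 4))))


class TestCorrelationMatrix:
    def stack_from_arrays(self, **arrays):
        return CovariateStack({k: grid_of(v) for k, v in arrays.items()})

    def test_diagonal_negation_and_hand_value(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        y = np.array([[1.0, 2.0], [4.0, 3.0]])
        stack = self.stack_from_arrays(x=x, neg=-x, y=y)
        c = correlation_matrix(stack)
        assert np.allclose(np.diag(c.to_numpy()), 1.0)
        assert np.isclose(c.loc["x", "neg"], -1.0)
        expected = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        assert np.isclose(c.loc["x", "y"], expected)
        assert np.allclose(c.to_numpy(), c.to_numpy().T)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        c1 = correlation_matrix(self.stack_from_arrays(a=a, b=b))
        c2 = correlation_matrix(self.stack_from_arrays(a=3 * a - 7, b=b))
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_zero_variance_flagged_not_zero(self):
        c = correlation_matrix(self.stack_from_arrays(
            a=np.ones((3, 3)), b=np.arange(9, dtype=float).reshape(3, 3)))
        assert np.isnan(c.loc["a", "b"])
        assert c.loc["a", "a"] == 1.0


class TestAdmissibleVariableSets:
    def brute(self, names, corr, thr):
        out = []
        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(names, r):
                idx = [names.index(v) for v in combo]
                if all(abs(corr[i][j]) < thr
                       for i, j in itertools.combinations(idx, 2)):
                    out.append(combo)
        return out

    def test_one_correlated_pair(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.9
        sets = admissible_variable_sets(["A", "B", "C"], corr, 0.7)
        assert sets == [("A",), ("B",), ("C",), ("A", "C"), ("B", "C")]

    def test_counting_extremes(self):
        n = 5
        free = admissible_variable_sets(list("abcde"), np.eye(n), 0.7)
        assert len(free) == 2 ** n - 1
        all_corr = np.ones((n, n))
        singles = admissible_variable_sets(list("abcde"), all_corr, 0.7)
        assert all(len(s) == 1 for s in singles) and len(singles) == n

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        n = 7
        r = rng.uniform(-1, 1, size=(n, n))
        corr = (r + r.T) / 2
        np.fill_diagonal(corr, 1.0)
        names = [f"v{i}" for i in range(n)]
        assert admissible_variable_sets(names, corr, 0.5) == \
            self.brute(names, corr.tolist(), 0.5)


class TestMapCorrelation:
    def test_self_and_complement(self):
        rng = np.random.default_rng(2)
        g = grid_of(rng.random((20, 20)))
        assert np.isclose(map_correlation(g, g), 1.0)
        comp = grid_of(1 - g.values)
        assert np.isclose(map_correlation(g, comp), -1.0)

    def test_matches_flat_pearson_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((20, 20)), rng.random((20, 20))
        got = map_correlation(grid_of(a), grid_of(b))
        assert np.isclose(got, np.corrcoef(a.ravel(), b.ravel())[0, 1])

    def test_zero_variance_undefined(self):
        g = grid_of(np.random.default_rng(0).random((5, 5)))
        flat = grid_of(np.ones((5, 5)))
        with pytest.warns(UserWarning):
            assert np.isnan(map_correlation(g, flat))


class TestFileIO:
    def test_ascii_roundtrip_value_exact(self, tmp_path):
        rng = np.random.default_rng(6)
        vals = rng.random((7, 9))
        mask = rng.random((7, 9)) > 0.2
        g = Grid(vals, mask, cell_size=1.5, origin=(12.5, -3.0))
        p = tmp_path / "g.asc"
        write_ascii_grid(g, p)
        g2 = read_ascii_grid(p)
        assert np.array_equal(g2.valid_mask, mask)
        assert np.array_equal(g2.values[mask], vals[mask])
        assert g2.cell_size == 1.5 and g2.origin == (12.5, -3.0)

    def test_ascii_categorical_roundtrip(self, tmp_path):
        cg = CategoricalGrid(np.arange(12).reshape(3, 4) % 3,
                             cell_size=2.0, origin=(0.0, 5.0))
        p = tmp_path / "c.asc"
        write_ascii_grid(cg, p)
        back = read_ascii_grid(p, categorical=True)
        assert np.array_equal(back.values, cg.values)

    def test_geotiff_roundtrip_within_float32(self, tmp_path):
        rng = np.random.default_rng(8)
        vals = rng.random((11, 13)) * 100
        mask = rng.random((11, 13)) > 0.1
        g = Grid(vals, mask, cell_size=1.0, origin=(100.0, 200.0))
        p = tmp_path / "g.tif"
        write_geotiff(g, p)
        g2 = read_geotiff(p)
        assert np.array_equal(g2.valid_mask, mask)
        assert np.allclose(g2.values[mask], vals[mask], rtol=1e-6)
        assert g2.origin == (100.0, 200.0)


class TestRegionPartition:
    def test_label_points_and_masks(self):
        labels = CategoricalGrid(
            np.repeat([[1, 2, 3]], 3, axis=0), cell_size=10.0)
        part = RegionPartition(labels)
        assert part.region_ids == [1, 2, 3]
        lab = part.label_points(np.array([5.0, 15.0, 25.0, -1.0]),
                                np.array([5.0, 5.0, 5.0, 5.0]))
        assert lab.tolist() == [1, 2, 3, -1]
        total = sum(part.mask_of(r).sum() for r in part.region_ids)
        assert total == labels.valid_mask.sum()
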