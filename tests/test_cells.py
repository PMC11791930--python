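"""Single-cell extraction: normalization, standardization, marker
selection, connected-component clustering against a flood-fill oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prism_ms import WorkflowError, da, ppm
from prism_ms import cells

from test_prescan import flood_fill_components


def matrix(values, mzs=None, stage=cells.RAW, coords=None):
    values = np.asarray(values, dtype=float)
    if mzs is None:
        mzs = 100.0 + np.arange(values.shape[1])
    return cells.FeatureMatrix(values, mzs, ids=list(range(len(values))),
                               stage=stage, coords=coords)


class TestNormalizeIS:
    IS = 208.1140

    def test_row_equal_to_is_becomes_ones(self):
        m = matrix([[4.0, 4.0, 4.0]], mzs=[100.0, self.IS, 300.0])
        out = cells.normalize_is(m, self.IS, da(0.01))
        np.testing.assert_allclose(out.values, 1.0)

    def test_is_column_identically_one(self, rng):
        m = matrix(rng.uniform(1, 10, (20, 4)), mzs=[100.0, 150.0, self.IS, 300.0])
        out = cells.normalize_is(m, self.IS, da(0.01))
        assert np.max(np.abs(out.values[:, 2] - 1.0)) == 0.0
        assert out.stage == cells.NORMALIZED

    def test_hand_division(self):
        m = matrix([[2.0, 4.0], [4.0, 4.0], [8.0, 4.0]], mzs=[self.IS, 150.0])
        out = cells.normalize_is(m, self.IS, da(0.01))
        np.testing.assert_allclose(out.values[:, 1], [2.0, 1.0, 0.5])

    def test_rows_without_is_signal_dropped_not_zero_filled(self):
        m = matrix([[2.0, 6.0], [0.0, 5.0], [4.0, 8.0]], mzs=[self.IS, 150.0])
        out = cells.normalize_is(m, self.IS, da(0.01))
        assert out.n_objects == 2
        np.testing.assert_allclose(out.values[:, 1], [3.0, 2.0])

    def test_missing_is_column_refused(self):
        m = matrix([[1.0, 2.0]])
        with pytest.raises(WorkflowError, match="no feature column"):
            cells.normalize_is(m, self.IS, da(0.005))


class TestNormalizeTIC:
    def test_hand_fractions(self):
        out = cells.normalize_tic(matrix([[1.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out.values, [[0.25, 0.25, 0.5]])

    def test_rows_sum_to_one(self, rng):
        out = cells.normalize_tic(matrix(rng.uniform(0.1, 5, (15, 6))))
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.1, 5, (4, 5))
        a = cells.normalize_tic(matrix(vals))
        b = cells.normalize_tic(matrix(vals * 7.0))
        np.testing.assert_allclose(a.values, b.values)

    def test_zero_sum_rows_dropped(self):
        out = cells.normalize_tic(matrix([[0.0, 0.0], [1.0, 3.0]]))
        assert out.n_objects == 1


class TestStandardize:
    def test_population_sd_convention(self):
        out = cells.z_standardize(matrix([[1.0], [2.0], [3.0]], stage=cells.NORMALIZED))
        np.testing.assert_allclose(out.values[:, 0],
                                   [-1.22474487, 0.0, 1.22474487])

    def test_columns_have_zero_mean_unit_sd(self, rng):
        out = cells.z_standardize(matrix(rng.normal(3, 2, (50, 4)),
                                         stage=cells.NORMALIZED))
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(out.values.std(axis=0) - 1) < 1e-9)

    def test_constant_column_zeroed_and_flagged(self):
        out = cells.z_standardize(matrix([[5.0, 1.0], [5.0, 2.0]],
                                         stage=cells.NORMALIZED))
        assert np.all(out.values[:, 0] == 0)
        assert out.constant_columns.tolist() == [True, False]

    def test_single_row_refused(self):
        with pytest.raises(WorkflowError, match="2 rows"):
            cells.z_standardize(matrix([[1.0, 2.0]], stage=cells.NORMALIZED))

    def test_gain_invariance_of_is_then_z_chain(self, rng):
        """Per-pixel multiplicative gain (laser/matrix variation) cancels."""
        vals = rng.uniform(1, 10, (30, 5))
        gains = rng.uniform(0.2, 5, 30)[:, None]
        mzs = [100.0, 150.0, 208.114, 250.0, 300.0]
        chain = lambda v: cells.z_standardize(
            cells.normalize_is(matrix(v, mzs=mzs), 208.114, da(0.01)))
        np.testing.assert_allclose(chain(vals).values, chain(vals * gains).values,
                                   atol=1e-9)


class TestMarkerSelection:
    def test_boundary_value_excluded(self):
        m = matrix(np.array([[-1.0], [0.0], [2.9], [3.0], [3.1]]),
                   mzs=[281.2485], stage=cells.STANDARDIZED)
        keep = cells.select_marker_pixels(m, 281.2485, da(0.01), z_min=3.0)
        assert keep.tolist() == [False, False, False, False, True]  # 3.0 removed

    def test_minus_infinity_keeps_all(self):
        m = matrix(np.array([[-5.0], [0.0]]), mzs=[281.2485], stage=cells.STANDARDIZED)
        keep = cells.select_marker_pixels(m, 281.2485, da(0.01), z_min=-np.inf)
        assert keep.all()

    def test_all_background_empty_selection(self):
        m = matrix(np.zeros((4, 1)), mzs=[281.2485], stage=cells.STANDARDIZED)
        assert not cells.select_marker_pixels(m, 281.2485, da(0.01)).any()

    def test_union_covers_both_single_marker_populations(self):
        # one lipid-A-only pixel, one lipid-B-only pixel
        m = matrix(np.array([[5.0, 0.0], [0.0, 5.0], [0.0, 0.0]]),
                   mzs=[786.6, 678.5], stage=cells.STANDARDIZED)
        keep = cells.select_union_pixels(m, [786.6, 678.5], da(0.01), z_min=3.0)
        assert keep.tolist() == [True, True, False]

    def test_single_marker_union_equals_plain_selection(self, rng):
        m = matrix(rng.normal(size=(20, 2)), mzs=[786.6, 678.5],
                   stage=cells.STANDARDIZED)
        np.testing.assert_array_equal(
            cells.select_union_pixels(m, [786.6], da(0.01), 1.0),
            cells.select_marker_pixels(m, 786.6, da(0.01), 1.0))

    def test_disjoint_selections_add(self):
        m = matrix(np.array([[5.0, 0.0]] * 3 + [[0.0, 5.0]] * 4),
                   mzs=[786.6, 678.5], stage=cells.STANDARDIZED)
        keep = cells.select_union_pixels(m, [786.6, 678.5], da(0.01), 3.0)
        assert keep.sum() == 7


class TestClusterCells:
    def test_l_shaped_blob_is_one_single_cell(self):
        objs = cells.cluster_cells(np.array([[0, 0], [0, 1], [1, 1]]))
        assert len(objs) == 1
        assert objs[0].n_pixels == 3
        assert objs[0].classification == cells.SINGLE_CELL

    def test_eight_pixel_blob_excluded_as_aggregate(self):
        coords = np.array([[x, 0] for x in range(8)])
        (obj,) = cells.cluster_cells(coords)
        assert obj.classification == cells.AGGREGATE

    def test_seven_pixel_blob_still_single_cell(self):
        coords = np.array([[x, 0] for x in range(7)])
        (obj,) = cells.cluster_cells(coords)
        assert obj.classification == cells.SINGLE_CELL

    def test_duplicate_pixels_refused(self):
        with pytest.raises(WorkflowError, match="unique"):
            cells.cluster_cells(np.array([[0, 0], [0, 0]]))

    def test_centroid_in_stage_units(self):
        (obj,) = cells.cluster_cells(np.array([[2, 3]]), pixel_size=20.0)
        assert obj.centroid == (pytest.approx(50.0), pytest.approx(70.0))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=40)
    def test_partition_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        flat = rng.choice(32 * 32, size=50, replace=False)
        coords = np.column_stack([flat % 32, flat // 32])
        grid = np.zeros((32, 32), dtype=bool)
        grid[coords[:, 1], coords[:, 0]] = True
        oracle = {frozenset((c, r) for r, c in comp)
                  for comp in flood_fill_components(grid)}
        objs = cells.cluster_cells(coords, max_single_cell_pixels=7)
        got = {frozenset(map(tuple, o.pixel_set)) for o in objs}
        assert got == oracle
        # partition property: disjoint and covering
        all_pixels = [tuple(p) for o in objs for p in o.pixel_set]
        assert len(all_pixels) == len(set(all_pixels)) == len(coords)


class TestCellMeanSpectra:
    def _pixel_matrix(self, coords, values):
        return cells.FeatureMatrix(np.asarray(values, float),
                                   [100.0, 200.0][:np.asarray(values).shape[1]],
                                   ids=[tuple(c) for c in coords],
                                   stage=cells.STANDARDIZED,
                                   coords=np.asarray(coords))

    def test_one_pixel_cell_is_its_row(self):
        m = self._pixel_matrix([[0, 0]], [[1.5, -2.0]])
        objs = cells.cluster_cells(np.array([[0, 0]]))
        out = cells.cell_mean_spectra(objs, m)
        np.testing.assert_allclose(out.values, [[1.5, -2.0]])

    def test_two_pixel_mean(self):
        m = self._pixel_matrix([[0, 0], [1, 0]], [[2.0, 0.0], [4.0, 0.0]])
        objs = cells.cluster_cells(np.array([[0, 0], [1, 0]]))
        out = cells.cell_mean_spectra(objs, m)
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_random_cell_matches_naive_loop(self, rng):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 1]])
        values = rng.normal(size=(5, 2))
        m = self._pixel_matrix(coords, values)
        objs = cells.cluster_cells(coords)
        out = cells.cell_mean_spectra(objs, m)
        naive = np.array([np.mean([values[i, j] for i in range(5)])
                          for j in range(2)])
        np.testing.assert_allclose(out.values[0], naive)

    def test_aggregates_omitted_from_statistics_matrix(self):
        coords = np.array([[x, 0] for x in range(8)] + [[0, 5]])
        values = np.ones((9, 1))
        m = cells.FeatureMatrix(values, [100.0], ids=[tuple(c) for c in coords],
                                stage=cells.STANDARDIZED, coords=coords)
        objs = cells.cluster_cells(coords)
        out = cells.cell_mean_spectra(objs, m)
        assert out.n_objects == 1  # only the isolated single cell

    def test_missing_pixel_refused(self):
        m = self._pixel_matrix([[0, 0]], [[1.0, 1.0]])
        objs = cells.cluster_cells(np.array([[5, 5]]))
        with pytest.raises(WorkflowError, match="missing"):
            cells.cell_mean_spectra(objs, m)
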