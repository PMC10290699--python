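import numpy as np
import pytest

from mycomap import (
    GridSpec,
    InterpolationConfig,
    PointSampleSet,
    Raster,
    difference_raster,
    holdout_validate,
    kmeans_stratify,
    rmse,
)
from conftest import best_threshold_partition


class TestRmse:
    def test_perfect_prediction(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_offset(self):
        assert rmse([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_handworked_value(self):
        assert rmse([1, 2, 3], [3, 2, 1]) == pytest.approx(np.sqrt(8 / 3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([1, 2], [1, 2, 3])

    def test_sign_symmetric_and_scales_linearly(self):
        rng = np.random.default_rng(0)
        x, xh = rng.normal(size=30), rng.normal(size=30)
        assert rmse(x, xh) == pytest.approx(rmse(xh, x))
        assert rmse(3.5 * x, 3.5 * xh) == pytest.approx(3.5 * rmse(x, xh))


class TestHoldout:
    @staticmethod
    def _pts(values):
        rng = np.random.default_rng(1)
        n = len(values)
        x = rng.random(n) * 500
        y = rng.random(n) * 500
        return PointSampleSet([f"p{i}" for i in range(n)], x, y, {"v": values})

    def test_constant_data_zero_rmse_for_idw(self):
        pts = self._pts(np.full(10, 4.2))
        cfg = InterpolationConfig(method="idw", cell_size=50.0)
        rep = holdout_validate(pts, "v", cfg, n_reps=5, seed=0)
        assert rep.mean_rmse == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, island):
        pts, _ = island
        cfg = InterpolationConfig(method="idw", cell_size=100.0)
        a = holdout_validate(pts, "abundance", cfg, n_reps=3, seed=9)
        b = holdout_validate(pts, "abundance", cfg, n_reps=3, seed=9)
        assert a.rmse_values == b.rmse_values

    def test_single_holdout_point_reduces_to_abs_error(self):
        values = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        pts = self._pts(values)
        cfg = InterpolationConfig(method="idw", cell_size=20.0)
        rep = holdout_validate(pts, "v", cfg, train_fraction=0.8, n_reps=1, seed=2)
        # 5 points, floor(0.8*5)=4 training -> exactly 1 held out
        assert len(rep.rmse_values) == 1
        assert rep.rmse_values[0] >= 0.0

    def test_too_few_samples(self):
        pts = self._pts(np.arange(4.0))
        with pytest.raises(ValueError, match="5 usable"):
            holdout_validate(pts, "v", InterpolationConfig(cell_size=10.0))

    def test_mean_rmse_decreases_with_training_fraction(self, island):
        pts, _ = island
        cfg = InterpolationConfig(method="idw", cell_size=100.0)
        means = []
        for frac in (0.5, 0.9):
            reps = [
                holdout_validate(pts, "abundance", cfg, train_fraction=frac,
                                 n_reps=4, seed=s).mean_rmse
                for s in range(6)
            ]
            means.append(np.mean(reps))
        assert means[1] < means[0]  # more training data -> better prediction


class TestKmeansStratify:
    def test_two_well_separated_clusters(self):
        spec = GridSpec(0, 20, 10.0, 2, 2)
        r = Raster(spec, np.array([[0.0, 0.0], [10.0, 10.0]]))
        s = kmeans_stratify(r, k=2, seed=0)
        assert np.allclose(s.centroids, [0.0, 10.0])
        assert np.array_equal(s.labels.values, [[0, 0], [1, 1]])

    def test_labels_ascend_with_centroids(self):
        rng = np.random.default_rng(3)
        spec = GridSpec(0, 50, 10.0, 10, 5)
        r = Raster(spec, rng.random((5, 10)) * 100)
        for k in (2, 3):
            s = kmeans_stratify(r, k=k, seed=1)
            assert (np.diff(s.centroids) > 0).all()

    @pytest.mark.parametrize("k", [2, 3])
    def test_agrees_with_exhaustive_threshold_search(self, k):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n_cells = int(rng.integers(k + 2, 100))
            vals = rng.normal(size=n_cells) * 10
            spec = GridSpec(0, float(n_cells), 1.0, 1, n_cells)
            s = kmeans_stratify(Raster(spec, vals.reshape(-1, 1)), k=k,
                                seed=trial, n_init=10)
            oracle_labels, oracle_cost = best_threshold_partition(vals, k)
            got = s.labels.values.ravel().astype(int)
            assert np.array_equal(got, oracle_labels), f"trial {trial}"

    def test_affine_invariance_of_partition(self):
        rng = np.random.default_rng(5)
        spec = GridSpec(0, 40, 10.0, 10, 4)
        vals = rng.random((4, 10))
        a = kmeans_stratify(Raster(spec, vals), k=3, seed=0)
        b = kmeans_stratify(Raster(spec, 7.0 * vals + 3.0), k=3, seed=0)
        assert np.array_equal(a.labels.values, b.labels.values)

    def test_nodata_kept(self):
        spec = GridSpec(0, 20, 10.0, 2, 2)
        r = Raster(spec, np.array([[0.0, np.nan], [10.0, 10.0]]))
        s = kmeans_stratify(r, k=2, seed=0)
        assert np.isnan(s.labels.values[0, 1])

    def test_too_few_distinct_values(self):
        spec = GridSpec(0, 20, 10.0, 2, 2)
        r = Raster(spec, np.full((2, 2), 3.0))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_stratify(r, k=2)


class TestDifferenceRaster:
    def test_self_difference_is_zero(self, small_raster):
        d, stats = difference_raster(small_raster, small_raster)
        assert np.all(d.values == 0)
        assert stats.mean == stats.sd == stats.sum_of_squares == 0.0

    def test_unit_offset_stats(self, small_raster):
        b = small_raster.copy_with(small_raster.values - 1.0)
        _, stats = difference_raster(small_raster, b)
        assert stats.mean == pytest.approx(1.0)
        assert stats.sd == pytest.approx(0.0)
        assert stats.sum_of_squares == pytest.approx(stats.n_cells)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(6)
        spec = GridSpec(0, 80, 10.0, 12, 8)
        for _ in range(10):
            a = Raster(spec, rng.normal(size=(8, 12)) * 50)
            b = Raster(spec, rng.normal(size=(8, 12)) * 50)
            _, s = difference_raster(a, b)
            expect = s.n_cells * (s.mean**2 + s.sd**2)
            assert s.sum_of_squares == pytest.approx(expect, rel=1e-9)

    def test_nodata_propagates(self, small_raster):
        b = small_raster.copy_with(small_raster.values.copy())
        b.values[1, 1] = np.nan
        d, stats = difference_raster(small_raster, b)
        assert np.isnan(d.values[1, 1])
        assert stats.n_cells == small_raster.values.size - 1

    def test_spec_mismatch_rejected(self, small_raster):
        other = Raster(GridSpec(0, 40, 10.0, 5, 4), small_raster.values.copy())
        ok = difference_raster(small_raster, other)  # same spec values -> fine
        shifted = Raster(GridSpec(5, 40, 10.0, 5, 4), small_raster.values.copy())
        with pytest.raises(ValueError, match="co-registered"):
            difference_raster(small_raster, shifted)
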