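import numpy as np
import pytest

from mycomap import (
    EmpiricalVariogram,
    GridSpec,
    InterpolationConfig,
    VariogramModel,
    empirical_variogram,
    fit_variogram_model,
    idw,
    interpolate,
    multilevel_bspline,
    ordinary_kriging,
)
from mycomap.interpolation import kriging_weights

# grid whose cell centers sit exactly on the island sampling lattice
ALIGNED = GridSpec(x_min=0.0, y_max=900.0, cell_size=100.0, n_cols=10, n_rows=9)


class TestIDW:
    def test_exact_at_data_points(self):
        # centers of ALIGNED cells coincide with the lattice points
        r = idw([150.0, 450.0], [250.0, 650.0], [3.0, 9.0], ALIGNED)
        assert r.values[6, 1] == 3.0  # row: (900-250)/100 -> 6
        assert r.values[2, 4] == 9.0

    @pytest.mark.parametrize("power", [0.5, 1.0, 2.0, 4.0])
    def test_midpoint_of_two_points_is_average(self, power):
        spec = GridSpec(-0.5, 0.5, 1.0, 11, 1)
        r = idw([0.0, 10.0], [0.0, 0.0], [2.0, 4.0], spec, power=power)
        assert r.values[0, 5] == pytest.approx(3.0)

    def test_single_point_gives_constant(self):
        spec = GridSpec(0, 10, 1.0, 10, 10)
        r = idw([3.3], [4.4], [7.0], spec)
        assert np.allclose(r.values, 7.0)

    def test_bounded_by_data_range(self):
        rng = np.random.default_rng(0)
        x, y, v = rng.random(20) * 100, rng.random(20) * 100, rng.normal(size=20)
        spec = GridSpec.from_points(x, y, 5.0)
        r = idw(x, y, v, spec)
        assert r.values.min() >= v.min() - 1e-12
        assert r.values.max() <= v.max() + 1e-12

    def test_invalid_power(self):
        with pytest.raises(ValueError, match="power"):
            idw([0.0], [0.0], [1.0], ALIGNED, power=0.0)


class TestEmpiricalVariogram:
    def test_two_points_half_squared_difference(self):
        ev = empirical_variogram([0.0, 100.0], [0.0, 0.0], [0.0, 2.0],
                                 n_lags=1, max_dist=150.0)
        assert ev.gamma[0] == pytest.approx(2.0)  # (1/2)(0-2)^2
        assert ev.pair_counts[0] == 1

    def test_equal_values_zero_semivariance(self):
        ev = empirical_variogram([0.0, 100.0], [0.0, 0.0], [5.0, 5.0],
                                 n_lags=1, max_dist=150.0)
        assert ev.gamma[0] == 0.0

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            empirical_variogram([1.0, 1.0], [2.0, 2.0], [0.0, 1.0])

    def test_white_noise_flat_at_sample_variance(self):
        rng = np.random.default_rng(1)
        x, y = np.meshgrid(np.arange(20.0), np.arange(20.0))
        v = rng.normal(size=400)
        ev = empirical_variogram(x.ravel(), y.ravel(), v)
        # each lag's gamma estimates the variance; tolerance 3 SE with
        # SE approximated by sqrt(2/N_k) * variance (chi-square spread)
        var = v.var()
        for g, n in zip(ev.gamma, ev.pair_counts):
            assert abs(g - var) < 3 * var * np.sqrt(2.0 / n) + 0.05 * var


class TestVariogramFit:
    def test_recovers_exact_spherical_curve(self):
        truth = VariogramModel("spherical", 0.1, 1.0, 300.0)
        h = np.linspace(20, 600, 15)
        ev = EmpiricalVariogram(h, truth(h), np.full(15, 100))
        m = fit_variogram_model(ev)
        assert m.kind == "spherical"
        assert m.nugget == pytest.approx(0.1, rel=0.05, abs=0.01)
        assert m.partial_sill == pytest.approx(1.0, rel=0.05)
        assert m.range == pytest.approx(300.0, rel=0.05)
        assert m.r2 > 0.999

    def test_flat_variogram_collapses_to_nugget_like_model(self):
        h = np.linspace(50, 500, 10)
        ev = EmpiricalVariogram(h, np.full(10, 2.0), np.full(10, 50))
        m = fit_variogram_model(ev)
        assert m(1e6) == pytest.approx(2.0, rel=0.01)  # total sill = variance
        # no structure: fitted curve is flat from the first lag onwards
        assert m(h[0]) == pytest.approx(2.0, rel=0.02)

    def test_r2_within_unit_interval(self):
        rng = np.random.default_rng(2)
        h = np.linspace(30, 400, 12)
        g = VariogramModel("exponential", 0.2, 0.8, 150.0)(h)
        g = g + rng.normal(0, 0.02, size=12)
        m = fit_variogram_model(ev := EmpiricalVariogram(h, g, np.full(12, 80)))
        assert 0.0 <= m.r2 <= 1.0

    def test_too_few_lags_rejected(self):
        ev = EmpiricalVariogram([1.0, 2.0], [0.5, 0.6], [3, 3])
        with pytest.raises(ValueError, match="lags"):
            fit_variogram_model(ev)

    def test_gamma_nondecreasing_for_all_kinds(self):
        h = np.linspace(0, 1000, 200)
        for kind in ("spherical", "exponential", "gaussian", "nugget"):
            g = VariogramModel(kind, 0.2, 0.8, 300.0)(h)
            assert (np.diff(g) >= -1e-12).all()


class TestOrdinaryKriging:
    def test_pure_nugget_predicts_mean_with_equal_weights(self):
        v = np.array([1.0, 2.0, 6.0])
        model = VariogramModel("nugget", 1.0, 0.0, 100.0)
        spec = GridSpec(0, 10, 1.0, 10, 10)
        r = ordinary_kriging([0.0, 1.0, 2.0], [0.0, 1.0, 0.0], v, model, spec)
        assert np.allclose(r.values, v.mean(), atol=1e-10)

    def test_equal_values_give_constant_surface(self):
        model = VariogramModel("spherical", 0.2, 0.8, 5.0)
        spec = GridSpec(0, 10, 1.0, 10, 10)
        r = ordinary_kriging([1.0, 7.0], [2.0, 8.0], [4.0, 4.0], model, spec)
        assert np.allclose(r.values, 4.0, atol=1e-9)

    def test_zero_nugget_exact_at_coincident_center(self):
        model = VariogramModel("spherical", 0.0, 1.0, 5.0)
        spec = GridSpec(0, 10, 1.0, 10, 10)
        r = ordinary_kriging([0.5, 3.5, 7.5], [9.5, 5.5, 0.5], [1.0, 2.0, 6.0],
                             model, spec)
        assert r.values[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_weights_sum_to_one_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x, y = rng.random(n) * 100, rng.random(n) * 100
            model = VariogramModel(
                str(rng.choice(["spherical", "exponential", "gaussian"])),
                float(rng.random() * 0.5), 0.5 + float(rng.random()),
                20.0 + float(rng.random()) * 100.0,
            )
            targets = rng.random((7, 2)) * 100
            lam = kriging_weights(x, y, model, targets)
            assert np.allclose(lam.sum(axis=0), 1.0, atol=1e-10)

    def test_duplicate_points_averaged(self):
        model = VariogramModel("spherical", 0.1, 1.0, 5.0)
        spec = GridSpec(0, 4, 1.0, 4, 4)
        a = ordinary_kriging([1.0, 1.0, 3.0], [1.0, 1.0, 3.0], [2.0, 4.0, 5.0],
                             model, spec)
        b = ordinary_kriging([1.0, 3.0], [1.0, 3.0], [3.0, 5.0], model, spec)
        assert np.allclose(a.values, b.values)

    def test_moving_window_matches_global_when_k_exceeds_n(self):
        rng = np.random.default_rng(4)
        x, y, v = rng.random(8) * 50, rng.random(8) * 50, rng.normal(size=8)
        model = VariogramModel("exponential", 0.1, 1.0, 20.0)
        spec = GridSpec(0, 50, 10.0, 5, 5)
        g = ordinary_kriging(x, y, v, model, spec, max_points=None)
        lw = ordinary_kriging(x, y, v, model, spec, max_points=50)
        assert np.allclose(g.values, lw.values)

    def test_variance_raster_nonnegative(self):
        model = VariogramModel("spherical", 0.1, 1.0, 30.0)
        spec = GridSpec(0, 50, 10.0, 5, 5)
        _, var = ordinary_kriging([5.0, 45.0], [5.0, 45.0], [0.0, 1.0], model,
                                  spec, return_variance=True)
        assert (var.values >= 0).all()


class TestMultilevelBspline:
    def test_single_point_honored_at_convergence(self):
        r = multilevel_bspline([450.0], [450.0], [5.0], ALIGNED, tol=1e-6)
        # (450, 450) is the center of cell (4, 4)
        assert r.values[4, 4] == pytest.approx(5.0, abs=1e-6)

    def test_constant_data_honored_at_data_locations(self):
        x = np.array([150.0, 450.0, 750.0, 250.0])
        y = np.array([150.0, 450.0, 750.0, 650.0])
        r = multilevel_bspline(x, y, np.full(4, 3.0), ALIGNED, tol=1e-8)
        rows = ((900.0 - y) / 100.0).astype(int)
        cols = (x / 100.0).astype(int)
        assert np.allclose(r.values[rows, cols], 3.0, atol=1e-8)

    def test_residual_nonincreasing_in_level(self):
        from mycomap.interpolation import _BsplineLevel

        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(10, 40))
            x, y = rng.random(n) * 900, rng.random(n) * 900
            resid = rng.normal(size=n)
            m = 4
            prev = np.abs(resid).max()
            for _level in range(8):
                lvl = _BsplineLevel(-1e-6, -1e-6, 900.0 + 2e-6, 900.0 + 2e-6, m, m)
                lvl.fit(x, y, resid)
                resid = resid - lvl(x, y)
                cur = np.abs(resid).max()
                assert cur <= prev + 1e-9
                prev = cur
                m *= 2
            assert prev < 1e-6  # converged on the data


class TestDispatcher:
    def test_idw_dispatch_equals_direct_call(self, island):
        pts, _ = island
        cfg = InterpolationConfig(method="idw", cell_size=50.0)
        via_cfg = interpolate(pts, "abundance", cfg)
        sub = pts.subset(pts.usable("abundance"))
        direct = idw(sub.x, sub.y, sub.attributes["abundance"], via_cfg.spec)
        assert np.array_equal(via_cfg.values, direct.values)

    def test_all_methods_share_gridspec(self, island):
        pts, _ = island
        specs = []
        for method in ("idw", "bspline", "kriging"):
            cfg = InterpolationConfig(method=method, cell_size=50.0)
            out = interpolate(pts, "abundance", cfg)
            r = out[0] if isinstance(out, tuple) else out
            specs.append(r.spec)
        assert specs[0] == specs[1] == specs[2]

    def test_kriging_autofit_returns_model(self, island):
        pts, _ = island
        cfg = InterpolationConfig(method="kriging", cell_size=100.0)
        raster, model = interpolate(pts, "abundance", cfg)
        assert isinstance(model, VariogramModel)
        assert model.kind in ("spherical", "exponential", "gaussian")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            InterpolationConfig(method="splines")


@pytest.mark.parametrize("method", ["idw", "bspline", "kriging"])
def test_translation_equivariance(method):
    rng = np.random.default_rng(6)
    x, y = rng.random(15) * 500, rng.random(15) * 500
    v = rng.normal(size=15)
    spec = GridSpec(0, 500, 100.0, 5, 5)
    model = VariogramModel("spherical", 0.1, 1.0, 200.0)
    dx, dy = 1234.0, -567.0
    spec2 = GridSpec(spec.x_min + dx, spec.y_max + dy, 100.0, 5, 5)
    if method == "idw":
        a, b = idw(x, y, v, spec), idw(x + dx, y + dy, v, spec2)
    elif method == "bspline":
        a = multilevel_bspline(x, y, v, spec, max_level=6)
        b = multilevel_bspline(x + dx, y + dy, v, spec2, max_level=6)
    else:
        a = ordinary_kriging(x, y, v, model, spec)
        b = ordinary_kriging(x + dx, y + dy, v, model, spec2)
    assert np.allclose(a.values, b.values, atol=1e-6)
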