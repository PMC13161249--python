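import numpy as np
import pytest

from ildselect.classify import fit_lda, posterior
from ildselect.contour import (
    CONTOUR_LEVELS,
    classify_new,
    evaluate,
    evaluate_grid,
    evaluate_points,
    fit_tps,
    render_pp_plot,
)
from ildselect.ild_core import compute_ilds
from ildselect.synthetic import generate_dataset, probe_dataset_spec


@pytest.fixture(scope="module")
def scattered(rng=None):
    rng = np.random.default_rng(100)
    pts = rng.uniform(0, 10, size=(40, 2))
    vals = rng.uniform(0, 1, size=40)
    return pts, vals


class TestFitTps:
    def test_constant_values_give_constant_surface(self, scattered):
        pts, _ = scattered
        model = fit_tps(pts, np.full(len(pts), 0.37), lam=0.0)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-8)
        np.testing.assert_allclose(model.affine, [0.37, 0.0, 0.0], atol=1e-8)
        q = np.random.default_rng(0).uniform(-5, 15, size=(30, 2))
        np.testing.assert_allclose(evaluate_points(model, q), 0.37, atol=1e-8)

    def test_affine_function_reproduced_exactly(self, scattered):
        """A thin-plate spline reproduces affine functions: fitting
        a + b1 x + b2 y returns that plane everywhere."""
        pts, _ = scattered
        vals = 0.3 + 0.05 * pts[:, 0] - 0.02 * pts[:, 1]
        model = fit_tps(pts, vals, lam=0.0)
        q = np.random.default_rng(1).uniform(-10, 20, size=(50, 2))
        expected = 0.3 + 0.05 * q[:, 0] - 0.02 * q[:, 1]
        np.testing.assert_allclose(evaluate_points(model, q), expected, atol=1e-7)

    def test_interpolation_at_lambda_zero(self, scattered):
        pts, vals = scattered
        model = fit_tps(pts, vals, lam=0.0)
        np.testing.assert_allclose(evaluate_points(model, pts), vals, atol=1e-8)

    def test_side_conditions(self, scattered):
        pts, vals = scattered
        model = fit_tps(pts, vals, lam=0.0)
        P = np.column_stack([np.ones(len(pts)), pts])
        np.testing.assert_allclose(P.T @ model.weights, 0.0, atol=1e-10)

    def test_matches_scipy_rbf_oracle(self, scattered):
        """Independent oracle: scipy's thin-plate RBFInterpolator produces
        the same surface at lambda = 0."""
        from scipy.interpolate import RBFInterpolator

        pts, vals = scattered
        model = fit_tps(pts, vals, lam=0.0)
        ref = RBFInterpolator(pts, vals, kernel="thin_plate_spline")
        q = np.random.default_rng(2).uniform(0, 10, size=(60, 2))
        np.testing.assert_allclose(
            evaluate_points(model, q), ref(q), atol=1e-7
        )

    def test_duplicate_points_conflicting_values_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [0.0, 0]])
        with pytest.raises(ValueError, match="conflicting"):
            fit_tps(pts, np.array([0.0, 1, 1, 0.5]), lam=0.0)

    def test_duplicate_points_lambda_zero_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [0.0, 0]])
        with pytest.raises(ValueError, match="lambda"):
            fit_tps(pts, np.array([0.0, 1, 1, 0.0]), lam=0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_tps(np.zeros((3, 2)), np.zeros(3), lam=1.0)

    def test_three_column_points_rejected(self):
        with pytest.raises(ValueError, match="two-ILD"):
            fit_tps(np.zeros((5, 3)), np.zeros(5), lam=1.0)

    def test_gcv_deterministic(self, scattered):
        pts, vals = scattered
        m1 = fit_tps(pts, vals, lam="gcv")
        m2 = fit_tps(pts, vals, lam="gcv")
        assert m1.lam == m2.lam
        np.testing.assert_array_equal(m1.gcv_scores, m2.gcv_scores)
        assert m1.lam == m1.gcv_lambdas[int(np.argmin(m1.gcv_scores))]


class TestEvaluate:
    def test_grid_equals_pointwise_loop(self, scattered):
        pts, vals = scattered
        model = fit_tps(pts, vals, lam=0.1)
        field = evaluate_grid(model, nx=21, ny=17)
        for iy in range(0, 17, 5):
            for ix in range(0, 21, 5):
                v = evaluate_points(
                    model, np.array([[field.x_axis[ix], field.y_axis[iy]]])
                )[0]
                assert field.raw_values[iy, ix] == pytest.approx(v, abs=1e-12)

    def test_clamped_vs_raw(self, scattered):
        pts, vals = scattered
        model = fit_tps(pts, vals, lam=0.0)
        field = evaluate_grid(model, 50, 50)
        assert field.values.min() >= 0.0 and field.values.max() <= 1.0
        np.testing.assert_array_equal(
            field.values, np.clip(field.raw_values, 0, 1)
        )

    def test_evaluate_dispatch(self, scattered):
        pts, vals = scattered
        model = fit_tps(pts, vals, lam=0.0)
        assert evaluate(model, pts[0]) == pytest.approx(vals[0], abs=1e-8)
        field = evaluate(model, grid=(30, 30))
        assert field.raw_values.shape == (30, 30)


class TestClassifyNew:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(200)
        X = np.vstack(
            [rng.normal(0, 1, size=(40, 2)), rng.normal(4, 1, size=(40, 2))]
        )
        y = np.array(["F"] * 40 + ["M"] * 40)
        lda = fit_lda(X, y)
        pp = posterior(lda, X)
        tps = fit_tps(X, pp, lam="gcv", group_labels=("F", "M"))
        return X, y, lda, tps

    def test_training_point_band_and_label(self, fitted):
        X, y, lda, _ = fitted
        pp = posterior(lda, X)
        hot = int(np.argmax(pp))
        tps0 = fit_tps(X, pp, lam=0.0, group_labels=("F", "M"))
        res = classify_new(tps0, X[hot][None])
        assert res.loc[0, "label"] == "M"
        assert res.loc[0, "band"] == "0.9-1.0"

    def test_midpoint_indeterminate(self, fitted):
        """A point interpolating to exactly the 0.5 threshold is labelled
        indeterminate."""
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        vals = np.array([0.2, 0.8, 0.2, 0.8])
        model = fit_tps(pts, vals, lam=0.0, group_labels=("F", "M"))
        res = classify_new(model, np.array([[0.5, 0.5]]))
        assert res.loc[0, "pp"] == pytest.approx(0.5, abs=1e-9)
        assert res.loc[0, "label"] == "indeterminate"

    def test_agreement_with_direct_posterior(self, fitted):
        """Surface-based classification agrees with direct DA posteriors
        for >= 95% of hold-out cases."""
        X, y, lda, tps = fitted
        rng = np.random.default_rng(201)
        hold = np.vstack(
            [rng.normal(0, 1, size=(50, 2)), rng.normal(4, 1, size=(50, 2))]
        )
        res = classify_new(tps, hold)
        direct = np.where(posterior(lda, hold) > 0.5, "M", "F")
        assert (res["label"].to_numpy() == direct).mean() >= 0.95

    def test_extrapolation_flagged(self, fitted):
        X, _, _, tps = fitted
        far = np.array([[100.0, 100.0]])
        res = classify_new(tps, far)
        assert bool(res.loc[0, "extrapolated"])
        inside = X.mean(axis=0)[None]
        assert not bool(classify_new(tps, inside).loc[0, "extrapolated"])

    def test_low_confidence_flag(self, fitted):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        vals = np.array([0.6, 0.6, 0.6, 0.6])
        model = fit_tps(pts, vals, lam=1e-6)
        res = classify_new(model, np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert res["low_confidence"].all()


class TestRenderPlot:
    @pytest.fixture(scope="class")
    def fitted_pipeline(self):
        spec, effect = probe_dataset_spec(seed=30, d=2.0, n_per_group=40)
        data, factor, smap, _ = generate_dataset(spec)
        mat = compute_ilds(data, smap)
        cols = [mat.names.index(n) for n in effect.names]
        X = mat.values[:, cols]
        y = factor.aligned_to(mat.individual_ids)
        lda = fit_lda(X, y, group_labels=factor.levels, predictor_names=effect.names)
        pp = posterior(lda, X)
        tps = fit_tps(X, pp, lam="gcv", group_labels=factor.levels)
        return tps, y

    def test_contour_levels_and_render(self, fitted_pipeline, tmp_path):
        tps, y = fitted_pipeline
        fig, field = render_pp_plot(tps, train_labels=y, path=str(tmp_path / "pp.png"))
        assert (tmp_path / "pp.png").exists()
        np.testing.assert_allclose(
            CONTOUR_LEVELS, np.arange(0, 1.05, 0.1), atol=1e-12
        )
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_half_contour_between_group_centroids(self, fitted_pipeline):
        """The 0.5 isoline separates the group centroids: the surface
        crosses 0.5 along the segment joining them."""
        tps, y = fitted_pipeline
        c_f = tps.train_points[np.asarray(y) == "F"].mean(axis=0)
        c_m = tps.train_points[np.asarray(y) == "M"].mean(axis=0)
        ts = np.linspace(0, 1, 200)
        seg = c_f[None] * (1 - ts[:, None]) + c_m[None] * ts[:, None]
        vals = evaluate_points(tps, seg) - 0.5
        assert vals[0] < 0 < vals[-1]
        assert (np.sign(vals[:-1]) != np.sign(vals[1:])).any()

    def test_constant_surface_no_interior_contours(self):
        pts = np.random.default_rng(5).uniform(0, 1, size=(10, 2))
        model = fit_tps(pts, np.full(10, 0.42), lam=0.0)
        fig, field = render_pp_plot(model)
        assert np.ptp(field.values) < 1e-8
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_render_deterministic(self, fitted_pipeline):
        tps, y = fitted_pipeline
        fig1, f1 = render_pp_plot(tps, train_labels=y)
        fig2, f2 = render_pp_plot(tps, train_labels=y)
        np.testing.assert_array_equal(f1.raw_values, f2.raw_values)
        assert len(fig1.axes[0].collections) == len(fig2.axes[0].collections)
        import matplotlib.pyplot as plt

        plt.close(fig1)
        plt.close(fig2)
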