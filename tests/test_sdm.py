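import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nichekit import sdm
from nichekit.raster import EnvStack


@pytest.fixture(scope="module")
def bg_two():
    rng = np.random.default_rng(3)
    return pd.DataFrame(rng.standard_normal((1500, 2)),
                        columns=["pc1", "pc2"])


@pytest.fixture(scope="module")
def planted(bg_two):
    """Presences drawn from a known log-linear suitability over bg."""
    rng = np.random.default_rng(4)
    true_beta = np.array([2.0, -1.0])
    w = np.exp(bg_two.to_numpy() @ true_beta)
    w = w / w.sum()
    idx = rng.choice(len(bg_two), 300, replace=True, p=w)
    return bg_two.iloc[idx], true_beta


class TestBuildFeatures:
    def test_linear_quadratic_count(self, bg_two):
        fs = sdm.build_features(bg_two, "lq")
        assert fs.n_features == 4

    def test_product_count_is_pairs(self):
        bg = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)),
                          columns=list("abc"))
        fs = sdm.build_features(bg, "p")
        assert fs.n_features == 3  # C(3,2)

    def test_hinge_is_zero_one_side_ramp_other(self, bg_two):
        fs = sdm.build_features(bg_two, "h", n_knots=3)
        knot = fs.knots["pc1"][1]
        below = fs._raw(np.array([[knot - 0.5, 0.0]]))
        at = fs._raw(np.array([[knot, 0.0]]))
        above = fs._raw(np.array([[knot + 0.5, 0.0]]))
        j_fwd = 2 * 1  # second knot of pc1, forward hinge
        assert at[0, j_fwd] == 0.0 and below[0, j_fwd] == 0.0
        assert above[0, j_fwd] == pytest.approx(0.5)
        j_rev = j_fwd + 1
        assert below[0, j_rev] == pytest.approx(0.5)
        assert above[0, j_rev] == 0.0

    def test_threshold_steps(self, bg_two):
        fs = sdm.build_features(bg_two, "t", n_knots=2)
        knot = fs.knots["pc2"][0]
        vals = fs._raw(np.array([[0.0, knot - 1e-9], [0.0, knot]]))
        j = 2 + 0  # pc2's first threshold feature
        assert vals[0, j] == 0.0 and vals[1, j] == 1.0

    def test_scaled_to_unit_interval_on_background(self, bg_two):
        fs = sdm.build_features(bg_two, "lqph", n_knots=4)
        F = fs.transform(bg_two)
        assert F.min() >= -1e-12 and F.max() <= 1 + 1e-12

    def test_validation(self, bg_two):
        with pytest.raises(ValueError, match="class"):
            sdm.build_features(bg_two, "")
        with pytest.raises(ValueError, match="product"):
            sdm.build_features(bg_two[["pc1"]], "p")


class TestFitMaxent:
    def test_huge_rm_zeroes_coefficients(self, bg_two, planted):
        pres, _ = planted
        fs = sdm.build_features(bg_two, "lq")
        m = sdm.fit_maxent(pres, bg_two, fs, rm=1e6)
        assert (m.coefficients == 0).all()
        raw = sdm.predict_points(m, bg_two)
        np.testing.assert_allclose(raw, raw[0])  # uniform

    def test_shifted_presences_get_positive_linear_weight(self, rng):
        bg = pd.DataFrame(rng.normal(0, 1, size=(800, 1)), columns=["x"])
        pres = pd.DataFrame(rng.normal(1.2, 0.6, size=(100, 1)),
                            columns=["x"])
        fs = sdm.build_features(bg, "l")
        m = sdm.fit_maxent(pres, bg, fs, rm=1.0)
        assert m.coefficients[0] > 0

    def test_matches_brute_force_on_tiny_instance(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame(rng.uniform(-1, 1, size=(20, 2)),
                          columns=["a", "b"])
        pres = bg.iloc[rng.choice(20, 12, replace=True,
                                  p=np.exp(bg["a"]) / np.exp(bg["a"]).sum())]
        fs = sdm.build_features(bg, "l")
        m = sdm.fit_maxent(pres, bg, fs, rm=0.5)
        F_pres = fs.transform(pres)
        F_bg = fs.transform(bg)
        lam = sdm.penalty_weights(fs, F_pres, F_bg, 0.5)
        f_opt = sdm.maxent_objective(m.coefficients, F_pres, F_bg, lam)
        # brute force: dense grid search over the two coefficients
        grid = np.arange(-6, 6, 0.02)
        best = min(sdm.maxent_objective(np.array([b1, b2]), F_pres, F_bg,
                                        lam)
                   for b1, b2 in itertools.product(grid, grid))
        assert f_opt <= best + 1e-4

    def test_deterministic_refit(self, bg_two, planted):
        pres, _ = planted
        fs = sdm.build_features(bg_two, "lq")
        a = sdm.fit_maxent(pres, bg_two, fs, rm=1.0)
        b = sdm.fit_maxent(pres, bg_two, fs, rm=1.0)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_monotone_regularization_path(self, bg_two, planted):
        pres, _ = planted
        fs = sdm.build_features(bg_two, "lq")
        norms = [np.abs(sdm.fit_maxent(pres, bg_two, fs, rm=rm,
                                       tol=1e-11, max_iter=20000)
                        .coefficients).sum()
                 for rm in (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(n1 >= n2 - 1e-4 for n1, n2 in zip(norms, norms[1:]))

    def test_recovers_planted_suitability_ranking(self, bg_two, planted):
        pres, true_beta = planted
        fs = sdm.build_features(bg_two, "lq")
        m = sdm.fit_maxent(pres, bg_two, fs, rm=1.0)
        fitted = sdm.predict_points(m, bg_two, output="cloglog")
        truth = bg_two.to_numpy() @ true_beta
        assert spearmanr(fitted, truth).statistic >= 0.9

    def test_too_few_presences_rejected(self, bg_two):
        fs = sdm.build_features(bg_two, "l")
        with pytest.raises(ValueError, match="presences"):
            sdm.fit_maxent(bg_two.head(5), bg_two, fs, rm=1.0)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self, bg_two, planted):
        pres, _ = planted
        fs = sdm.build_features(bg_two, "lq")
        return sdm.fit_maxent(pres, bg_two, fs, rm=1.0)

    def _stack_from(self, df):
        n = len(df)
        side = int(np.sqrt(n))
        data = df.to_numpy()[:side * side].T.reshape(2, side, side)
        return EnvStack(["pc1", "pc2"], data, x0=0, y0=side)

    def test_raw_sums_to_one_on_calibration_background(self, bg_two,
                                                       fitted):
        st = self._stack_from(bg_two)
        m = sdm.predict(fitted, st, output="raw")
        assert np.nansum(m.values) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_model_cloglog_constant(self, bg_two, planted):
        pres, _ = planted
        fs = sdm.build_features(bg_two, "l")
        m = sdm.fit_maxent(pres, bg_two, fs, rm=1e9)
        out = sdm.predict_points(m, bg_two, output="cloglog")
        np.testing.assert_allclose(out, 1 - np.exp(-1.0), atol=1e-9)

    def test_no_masking_on_calibration_stack(self, bg_two, fitted):
        st = self._stack_from(bg_two)
        m = sdm.predict(fitted, st, extrapolation="mask")
        assert np.isfinite(m.values).all()

    def test_out_of_range_cells_masked_or_clamped(self, bg_two, fitted):
        st = self._stack_from(bg_two)
        shifted = EnvStack(st.layer_names, st.data + 100.0, x0=0,
                           y0=st.shape[0])
        with pytest.warns(UserWarning, match="calibration range"):
            masked = sdm.predict(fitted, shifted, extrapolation="mask")
        assert np.isnan(masked.values).all()
        clamped = sdm.predict(fitted, shifted, extrapolation="clamp")
        assert np.isfinite(clamped.values).all()

    def test_output_bounds(self, bg_two, fitted):
        st = self._stack_from(bg_two)
        m = sdm.predict(fitted, st, output="cloglog")
        vals = m.values[np.isfinite(m.values)]
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_at_points_round_trip(self, bg_two, fitted):
        st = self._stack_from(bg_two)
        m = sdm.predict(fitted, st, output="cloglog")
        x, y = st.xy(np.array([2, 3]), np.array([1, 4]))
        np.testing.assert_allclose(m.at_points(x, y),
                                   m.values[[2, 3], [1, 4]])
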