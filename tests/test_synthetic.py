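import numpy as np
import pytest
from scipy import stats

from nichekit.synthetic import (LandscapeSpec, VirtualSpecies,
                                analytic_density_overlap, analytic_overlap,
                                make_landscape, make_paleo_stack,
                                sample_occurrences, suitability)


def morans_i(band: np.ndarray) -> float:
    """Rook-adjacency Moran's I (independent spatial-autocorrelation
    oracle)."""
    z = band - band.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    n_pairs = z[:-1, :].size + z[:, :-1].size
    return (num / n_pairs) / (z ** 2).mean()


class TestMakeLandscape:
    def test_deterministic_given_seed(self):
        spec = LandscapeSpec(20, 20, 1.0, 2, 3.0, seed=1)
        a = make_landscape(spec)
        b = make_landscape(LandscapeSpec(20, 20, 1.0, 2, 3.0, seed=1))
        np.testing.assert_array_equal(a.data, b.data)
        c = make_landscape(LandscapeSpec(20, 20, 1.0, 2, 3.0, seed=2))
        assert not np.array_equal(a.data, c.data)

    def test_inter_layer_correlation_recovered(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        st = make_landscape(LandscapeSpec(200, 200, 1.0, 2, 5.0,
                                          inter_layer_corr=corr, seed=3))
        r = np.corrcoef(st.data[0].ravel(), st.data[1].ravel())[0, 1]
        assert abs(r - 0.9) < 0.1

    def test_autocorrelation_controlled_by_range(self):
        rough = make_landscape(LandscapeSpec(80, 80, 1.0, 1, 1e-9, seed=4))
        smooth = make_landscape(LandscapeSpec(80, 80, 1.0, 1, 6.0, seed=4))
        assert abs(morans_i(rough.data[0])) < 0.05
        assert morans_i(smooth.data[0]) > 0.5

    def test_invalid_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])  # not positive definite
        with pytest.raises(ValueError, match="positive definite"):
            LandscapeSpec(20, 20, 1.0, 2, 3.0, inter_layer_corr=bad)
        with pytest.raises(ValueError):
            LandscapeSpec(5, 20, 1.0, 2, 3.0)


class TestSampleOccurrences:
    def test_deterministic_and_on_cells(self, small_stack):
        sp = VirtualSpecies([0, 0, 0], 0.5 * np.eye(3))
        a = sample_occurrences(sp, small_stack, 50, seed=7)
        b = sample_occurrences(sp, small_stack, 50, seed=7)
        assert a.df.equals(b.df)
        # coordinates are cell centers
        assert np.allclose((a.df["x"] - 0.5) % 1.0, 0.0)

    def test_mask_respected(self, small_stack):
        sp = VirtualSpecies([0, 0, 0], np.eye(3))
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[:, :10] = True
        occ = sample_occurrences(sp, small_stack, 30, region_mask=mask,
                                 seed=1)
        rows, cols = small_stack.rowcol(occ.df["x"], occ.df["y"])
        assert mask[rows, cols].all()

    def test_too_small_mask_errors(self, small_stack):
        sp = VirtualSpecies([0, 0, 0], np.eye(3))
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[0, :5] = True
        with pytest.raises(ValueError, match="positive-suitability"):
            sample_occurrences(sp, small_stack, 30, region_mask=mask)

    def test_sampled_environment_mean_near_niche_center(self):
        st = make_landscape(LandscapeSpec(150, 150, 1.0, 2, 3.0, seed=8))
        mu = np.array([0.4, -0.2])
        sp = VirtualSpecies(mu, 0.04 * np.eye(2))
        occ = sample_occurrences(sp, st, 2000, seed=9)
        env = st.extract(occ.df["x"].to_numpy(), occ.df["y"].to_numpy())
        np.testing.assert_allclose(env.mean(axis=0), mu, atol=0.08)

    def test_tight_niche_concentrates_on_best_cells(self, small_stack):
        mu = small_stack.data[:, 20, 20]
        sp = VirtualSpecies(mu, 2e-3 * np.eye(3))
        occ = sample_occurrences(sp, small_stack, 3, seed=3)
        env = small_stack.extract(occ.df["x"].to_numpy(),
                                  occ.df["y"].to_numpy())
        d = np.linalg.norm(env.to_numpy() - mu, axis=1)
        all_env = small_stack.table().to_numpy()
        d_all = np.sort(np.linalg.norm(all_env - mu, axis=1))
        # draws sit among the cells whose environment is nearest the
        # niche center
        assert (np.sort(d) <= d_all[9] + 1e-12).all()


class TestPaleoStack:
    def test_zero_shift_zero_noise_is_identity(self, small_stack):
        p = make_paleo_stack(small_stack, [0, 0, 0], 0.0)
        np.testing.assert_array_equal(p.data, small_stack.data)

    def test_shift_applied_exactly(self, small_stack):
        p = make_paleo_stack(small_stack, [2.0, 0.0, 0.0], 0.0)
        np.testing.assert_allclose(
            p.data[0].mean() - small_stack.data[0].mean(), 2.0)
        np.testing.assert_array_equal(p.data[1], small_stack.data[1])

    def test_noise_sd_as_stated(self, small_stack):
        p = make_paleo_stack(small_stack, [0, 0, 0], 1.0, seed=5)
        diff = p.data[0] - small_stack.data[0]
        assert abs(diff.std() - 1.0) < 1e-9

    def test_shift_length_mismatch(self, small_stack):
        with pytest.raises(ValueError, match="length"):
            make_paleo_stack(small_stack, [1.0, 2.0], 0.0)


class TestAnalyticOverlap:
    @pytest.mark.parametrize("alpha", [0.5, 0.95, 0.99])
    def test_self_overlap_equals_alpha(self, alpha):
        sp = VirtualSpecies([0, 1], [[1.0, 0.3], [0.3, 0.8]])
        ov = analytic_overlap(sp, sp, alpha, n_mc=400_000, seed=1)
        assert abs(ov - alpha) < 0.005

    def test_one_dimensional_closed_form(self):
        a = VirtualSpecies([0.0], [[1.0]])
        b = VirtualSpecies([2.0], [[1.0]])
        got = analytic_overlap(a, b, 0.95)
        c = np.sqrt(stats.chi2.ppf(0.95, 1))   # = 1.95996...
        want = stats.norm.cdf(2 + c) - stats.norm.cdf(2 - c)
        assert abs(got - want) < 1e-12

    def test_separated_niches_overlap_vanishes(self):
        a = VirtualSpecies([0, 0], np.eye(2))
        b = VirtualSpecies([50, 50], np.eye(2))
        assert analytic_overlap(a, b, 0.95, n_mc=50_000, seed=2) == 0.0

    def test_alpha_validation(self):
        sp = VirtualSpecies([0.0], [[1.0]])
        with pytest.raises(ValueError, match="alpha"):
            analytic_overlap(sp, sp, 1.5)


class TestAnalyticDensityOverlap:
    def test_identical_niches_overlap_one(self):
        sp = VirtualSpecies([0, 0], np.eye(2))
        assert abs(analytic_density_overlap(sp, sp) - 1.0) < 1e-6

    def test_one_dimensional_closed_form(self):
        # equal-variance normals d apart: overlap = 2 Phi(-d/2)
        a = VirtualSpecies([0.0], [[1.0]])
        b = VirtualSpecies([1.0], [[1.0]])
        want = 2 * stats.norm.cdf(-0.5)
        assert abs(analytic_density_overlap(a, b, n_grid=2000) - want) < 1e-4

    def test_distant_niches_vanish(self):
        a = VirtualSpecies([0, 0], np.eye(2))
        b = VirtualSpecies([30, 0], np.eye(2))
        assert analytic_density_overlap(a, b) < 1e-6


def test_virtual_species_validation():
    with pytest.raises(ValueError, match="positive definite"):
        VirtualSpecies([0, 0], [[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        VirtualSpecies([0, 0], [[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(ValueError, match="detection_scale"):
        VirtualSpecies([0.0], [[1.0]], detection_scale=0.0)


def test_suitability_peaks_at_niche_center(small_stack):
    mu = small_stack.data[:, 5, 5]
    sp = VirtualSpecies(mu, np.eye(3))
    s = suitability(sp, small_stack)
    assert s[5, 5] == pytest.approx(1.0)
    assert (s <= 1.0 + 1e-12).all()
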