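import numpy as np
import pandas as pd
import pytest

from nichekit import selection


class TestCandidateGrid:
    def test_default_rm_ladder(self):
        rm = selection.default_rm_values()
        assert len(rm) == 17
        assert rm[:10] == [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        assert rm[10:] == [2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0]

    def test_all_class_subsets(self):
        subs = selection.all_class_subsets()
        assert len(subs) == 31
        assert len(set(subs)) == 31
        assert "lqpht" in subs and "l" in subs

    def test_full_grid_size(self):
        grid = selection.candidate_grid(selection.default_rm_values(),
                                        selection.all_class_subsets(),
                                        ["pc1-4", "pc1-5", "pc1-6"])
        assert len(grid) == 1581

    def test_count_is_product_of_axis_sizes(self):
        grid = selection.candidate_grid([1.0, 2.0], ["l", "lq", "h"],
                                        ["a"])
        assert len(grid) == 6
        assert len(selection.candidate_grid([1.0], ["l"], ["a"])) == 1

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            selection.candidate_grid([], ["l"], ["a"])


class TestSplit:
    def test_75_25(self):
        train, test = selection.split_occurrences(100, seed=0)
        assert len(train) == 75 and len(test) == 25

    def test_deterministic(self):
        a = selection.split_occurrences(60, seed=5)
        b = selection.split_occurrences(60, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_partition(self):
        train, test = selection.split_occurrences(41, seed=1)
        assert set(train) | set(test) == set(range(41))
        assert not set(train) & set(test)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            selection.split_occurrences(5)


class TestOmissionRate:
    def test_test_equals_train_bounded_by_E(self, rng):
        s = rng.uniform(0, 1, 200)
        assert selection.omission_rate(s, s, E=0.05) <= 0.05

    def test_all_above_training_max(self, rng):
        train = rng.uniform(0, 0.5, 100)
        test = rng.uniform(0.6, 1.0, 40)
        assert selection.omission_rate(train, test) == 0.0

    def test_twenty_value_brute_force(self):
        train = np.arange(1, 21) / 20.0          # 0.05 .. 1.00
        test = np.array([0.01, 0.05, 0.08, 0.12, 0.5, 0.9])
        thr = np.quantile(train, 0.05)
        want = np.mean(test < thr)               # direct count oracle
        assert selection.omission_rate(train, test, 0.05) == want


class TestPartialRoc:
    def test_planted_signal_detected(self, rng):
        bg = rng.uniform(0, 1, 1500)
        test = rng.uniform(0.5, 1.0, 60)
        ratio, p = selection.partial_roc(bg, test, n_boot=200, seed=0)
        assert ratio > 1.1
        assert p <= 0.05

    def test_null_ratio_near_one(self, rng):
        bg = rng.uniform(0, 1, 1500)
        test = rng.choice(bg, 400)
        ratio, p = selection.partial_roc(bg, test, n_boot=200, seed=1)
        assert abs(ratio - 1.0) < 0.1

    def test_perfect_separation_maximal_ratio(self, rng):
        bg = rng.uniform(0, 0.4, 1000)
        test = rng.uniform(0.6, 1.0, 50)
        ratio, p = selection.partial_roc(bg, test, n_boot=100, seed=2)
        # sensitivity 1 down to area fraction 0: pAUC 1 vs 0.5 under null
        assert ratio >= 1.9
        assert p == 0.0

    def test_constant_map_flagged(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            ratio, p = selection.partial_roc(np.full(100, 0.3),
                                             rng.uniform(0, 1, 20))
        assert np.isnan(ratio)

    def test_too_few_test_points(self, rng):
        with pytest.raises(ValueError, match="test points"):
            selection.partial_roc(rng.uniform(0, 1, 100),
                                  rng.uniform(0, 1, 5))


class TestAicc:
    def test_spot_value(self):
        # 2*5 + 200 + 2*5*6/94
        assert selection.aicc(-100.0, 5, 100) == pytest.approx(
            210.63829787234042)

    def test_zero_parameters(self):
        assert selection.aicc(-50.0, 0, 30) == pytest.approx(100.0)

    def test_monotone_in_k_at_equal_likelihood(self):
        vals = [selection.aicc(-80.0, k, 60) for k in range(0, 6)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_undefined_when_overparameterized(self):
        assert np.isnan(selection.aicc(-10.0, 10, 11))


class TestSelectModels:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["proc_p", "omission_rate",
                                           "aicc"])

    def test_single_passing_candidate(self):
        t = self._table([(0.0, 0.01, 100.0)])
        out = selection.select_models(t)
        assert out["selected"].iloc[0]
        assert out["delta_aicc"].iloc[0] == 0.0

    def test_delta_rule_excludes_worse_model(self):
        t = self._table([(0.0, 0.01, 100.0), (0.0, 0.01, 103.0)])
        out = selection.select_models(t)
        assert list(out["selected"]) == [True, False]
        assert list(out["delta_aicc"]) == [0.0, 3.0]

    def test_delta_baseline_restricted_to_passing(self):
        # the lowest-AICc candidate fails the omission filter; delta is
        # computed against the best PASSING candidate
        t = self._table([(0.0, 0.50, 90.0), (0.0, 0.01, 100.0)])
        out = selection.select_models(t)
        assert out["delta_aicc"].iloc[1] == 0.0
        assert out["selected"].iloc[1]
        assert not out["selected"].iloc[0]

    def test_nothing_passes_warns(self):
        t = self._table([(0.9, 0.5, 100.0), (0.8, 0.4, 90.0)])
        with pytest.warns(UserWarning, match="no candidate"):
            out = selection.select_models(t)
        assert not out["selected"].any()
        assert out["delta_aicc"].min() == 0.0

    def test_idempotent_and_order_independent(self):
        t = self._table([(0.0, 0.01, 100.0), (0.0, 0.02, 101.0),
                         (0.2, 0.01, 99.0)])
        once = selection.select_models(t)
        twice = selection.select_models(once[["proc_p", "omission_rate",
                                              "aicc"]])
        pd.testing.assert_frame_equal(
            once[["delta_aicc", "selected"]],
            twice[["delta_aicc", "selected"]])
        shuffled = selection.select_models(t.iloc[[2, 0, 1]])
        assert list(shuffled.sort_index()["selected"]) == \
            list(once["selected"])


def test_run_calibration_selects_on_planted_signal():
    """End-to-end: presences from a strong log-linear signal over the
    background yield at least one selected candidate with low omission."""
    rng = np.random.default_rng(9)
    bg = pd.DataFrame(rng.standard_normal((1200, 2)),
                      columns=["pc1", "pc2"])
    w = np.exp(bg.to_numpy() @ np.array([2.5, -1.5]))
    pres = bg.iloc[rng.choice(len(bg), 200, replace=True, p=w / w.sum())]
    cands = selection.candidate_grid([0.5, 1.0], ["l", "lq"], ["pcs"])
    table = selection.run_calibration(
        pres.reset_index(drop=True), bg, cands,
        {"pcs": ["pc1", "pc2"]}, n_boot=100, seed=2)
    assert len(table) == 4
    assert table["selected"].any()
    sel = table[table["selected"]]
    assert (sel["omission_rate"] < 0.05).all()
    assert (sel["delta_aicc"] <= 2.0).all()
    assert table["delta_aicc"].min() == 0.0
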