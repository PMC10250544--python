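"""Candidate-model calibration and selection.

Enumerates a regularization-multiplier x feature-class x predictor-set
grid, evaluates each candidate on a fixed 75/25 presence split with
partial ROC and omission rate, scores all candidates with AICc on the full
data, and keeps those with significant partial ROC, omission rate below E
and delta-AICc <= 2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdm import ConvergenceError, FeatureSet, build_features, fit_maxent, \
    predict_points

__all__ = ["CandidateSpec", "candidate_grid", "default_rm_values",
           "all_class_subsets", "split_occurrences", "omission_rate",
           "partial_roc", "aicc", "select_models", "run_calibration"]


@dataclass(frozen=True)
class CandidateSpec:
    rm: float
    classes: str
    predictor_set: str

    def __post_init__(self):
        if self.rm <= 0:
            raise ValueError("rm must be positive")
        if not self.classes:
            raise ValueError("classes must be non-empty")


def default_rm_values() -> list[float]:
    """The canonical 17-value regularization-multiplier ladder:
    0.1..1.0 by 0.1, 2..6 by 1, then 8 and 10."""
    return ([round(0.1 * i, 1) for i in range(1, 11)]
            + [2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0])


def all_class_subsets(classes: str = "lqpht") -> list[str]:
    """All 2^m - 1 non-empty feature-class combinations (31 for 5)."""
    out = []
    for r in range(1, len(classes) + 1):
        for combo in itertools.combinations(classes, r):
            out.append("".join(combo))
    return out


def candidate_grid(rm_values, class_subsets, predictor_sets
                   ) -> list[CandidateSpec]:
    """Cartesian product of the three calibration axes, stable order."""
    if not (list(rm_values) and list(class_subsets)
            and list(predictor_sets)):
        raise ValueError("all grid axes must be non-empty")
    return [CandidateSpec(rm, cls, ps)
            for ps in predictor_sets
            for cls in class_subsets
            for rm in rm_values]


def split_occurrences(n_or_index, train_frac: float = 0.75,
                      seed: int | None = 0):
    """One fixed random train/test split, reused across all candidates."""
    if np.isscalar(n_or_index):
        idx = np.arange(int(n_or_index))
    else:
        idx = np.asarray(n_or_index)
    n = idx.size
    if n < 8:
        raise ValueError("need at least 8 occurrences to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return np.sort(idx[perm[:n_train]]), np.sort(idx[perm[n_train:]])


def omission_rate(suit_train: np.ndarray, suit_test: np.ndarray,
                  E: float = 0.05) -> float:
    """Share of test suitabilities strictly below the E-quantile of the
    training suitabilities (the lowest-E% training presences are treated
    as acceptable omission)."""
    suit_train = np.asarray(suit_train, float)
    suit_test = np.asarray(suit_test, float)
    if suit_train.size == 0 or suit_test.size == 0:
        raise ValueError("empty train or test suitabilities")
    thr = np.quantile(suit_train, E)
    return float(np.mean(suit_test < thr))


def _pauc_ratio(bg: np.ndarray, test: np.ndarray, E: float) -> float:
    """Partial AUC ratio of sensitivity vs proportion-of-area curves,
    restricted to sensitivity >= 1 - E, against the null diagonal."""
    thresholds = np.unique(np.concatenate([bg, test, [-np.inf]]))
    # descending thresholds -> increasing area fraction and sensitivity
    thr = thresholds[::-1]
    area = np.searchsorted(np.sort(bg), thr, side="left")
    area = 1.0 - area / bg.size          # fraction of area >= thr
    sens = np.searchsorted(np.sort(test), thr, side="left")
    sens = 1.0 - sens / test.size        # fraction of test >= thr
    keep = sens >= 1.0 - E
    x, y = area[keep], sens[keep]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if x.size < 2 or x[-1] <= x[0]:
        return np.nan
    # model partial AUC against the null diagonal over the same x grid
    p_model = np.trapezoid(y, x)
    p_null = np.trapezoid(x, x)
    if p_null <= 0:
        return np.nan
    return float(p_model / p_null)


def partial_roc(suit_bg: np.ndarray, suit_test: np.ndarray,
                E: float = 0.05, n_boot: int = 500,
                boot_frac: float = 0.5, seed: int | None = 0
                ) -> tuple[float, float]:
    """Partial-ROC significance of a model.

    The AUC of the (proportion of area predicted, sensitivity) curve over
    sensitivities >= 1-E is divided by the null-diagonal AUC on the same
    region; bootstrapping ``boot_frac`` of the test points ``n_boot``
    times gives the mean ratio and p = share of ratios <= 1.
    """
    suit_bg = np.asarray(suit_bg, float)
    suit_bg = suit_bg[np.isfinite(suit_bg)]
    suit_test = np.asarray(suit_test, float)
    if suit_test.size < 10:
        raise ValueError("need at least 10 test points")
    if np.ptp(suit_bg) == 0:
        warnings.warn("constant suitability map: partial ROC undefined",
                      stacklevel=2)
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    m = max(2, int(round(boot_frac * suit_test.size)))
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sub = rng.choice(suit_test, size=m, replace=True)
        ratios[b] = _pauc_ratio(suit_bg, sub, E)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        return np.nan, np.nan
    return float(ratios.mean()), float(np.mean(ratios <= 1.0))


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: 2k - 2 lnL + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        return np.nan
    return float(2 * k - 2 * log_likelihood + 2 * k * (k + 1) / (n - k - 1))


def select_models(table: pd.DataFrame, proc_alpha: float = 0.05,
                  or_max: float = 0.05, delta_max: float = 2.0,
                  delta_over_all: bool = False) -> pd.DataFrame:
    """Apply the three selection filters and compute delta-AICc.

    The delta baseline is the minimum AICc among candidates passing the
    significance and omission filters (set ``delta_over_all`` to baseline
    on every candidate instead).  Returns the table with ``delta_aicc``
    and ``selected`` columns.
    """
    if table.empty:
        raise ValueError("empty selection table")
    out = table.copy()
    pass_stat = (out["proc_p"] < proc_alpha) & (out["omission_rate"] < or_max)
    pool = out if delta_over_all else out[pass_stat]
    if pool.empty or not np.isfinite(pool["aicc"]).any():
        warnings.warn("no candidate passes the significance and omission "
                      "filters; reporting best-by-AICc for diagnostics",
                      stacklevel=2)
        base = np.nanmin(out["aicc"]) if np.isfinite(out["aicc"]).any() \
            else np.nan
        out["delta_aicc"] = out["aicc"] - base
        out["selected"] = False
        return out
    base = np.nanmin(pool["aicc"])
    out["delta_aicc"] = out["aicc"] - base
    out["selected"] = pass_stat & (out["delta_aicc"] <= delta_max)
    return out


def run_calibration(presences: pd.DataFrame, background: pd.DataFrame,
                    candidates: list[CandidateSpec],
                    predictor_sets: dict[str, list[str]],
                    E: float = 0.05, n_boot: int = 100,
                    n_knots: int = 10, seed: int | None = 0,
                    proc_alpha: float = 0.05, or_max: float = 0.05,
                    delta_max: float = 2.0) -> pd.DataFrame:
    """Fit and evaluate every candidate; returns the selection table.

    ``presences`` / ``background`` hold predictor values per record/cell;
    the same seeded 75/25 presence split is reused for every candidate.
    """
    train_idx, test_idx = split_occurrences(len(presences), seed=seed)
    rows = []
    feature_cache: dict[tuple, FeatureSet] = {}
    for cand in candidates:
        preds = predictor_sets[cand.predictor_set]
        key = (cand.predictor_set, cand.classes)
        if key not in feature_cache:
            feature_cache[key] = build_features(background[preds],
                                                cand.classes, n_knots)
        fs = feature_cache[key]
        row = {"rm": cand.rm, "classes": cand.classes,
               "predictor_set": cand.predictor_set}
        try:
            model = fit_maxent(presences[preds].iloc[train_idx],
                               background[preds], fs, rm=cand.rm)
            suit_train = predict_points(model,
                                        presences[preds].iloc[train_idx])
            suit_test = predict_points(model,
                                       presences[preds].iloc[test_idx])
            suit_bg = predict_points(model, background[preds])
            o_rate = omission_rate(suit_train, suit_test, E)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                auc_ratio, p = partial_roc(suit_bg, suit_test, E,
                                           n_boot=n_boot, seed=seed)
            full = fit_maxent(presences[preds], background[preds], fs,
                              rm=cand.rm)
            lnl = float(np.sum(np.log(
                predict_points(full, presences[preds]))))
            k = full.n_parameters
            row.update(mean_auc_ratio=auc_ratio, proc_p=p,
                       omission_rate=o_rate,
                       aicc=aicc(lnl, k, len(presences)),
                       n_parameters=k)
        except (ConvergenceError, ValueError) as err:
            row.update(mean_auc_ratio=np.nan, proc_p=np.nan,
                       omission_rate=np.nan, aicc=np.nan,
                       n_parameters=0, error=str(err))
        rows.append(row)
    table = pd.DataFrame(rows)
    return select_models(table, proc_alpha, or_max, delta_max)
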