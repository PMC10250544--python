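"""Maximum-entropy presence–background suitability model.

The model is the Gibbs distribution over background cells,
``P(cell) = exp(beta' h(x)) / Z``, fitted by maximizing the mean feature
score of presences minus log Z, with per-feature L1 penalties
``lambda_j = rm * tau(class_j, n_presences) * sd_j / sqrt(n_presences)``.
Features are the classical classes: linear, quadratic, product, hinge and
threshold transforms of the predictors, min-max scaled by background
statistics.  The problem is convex; a FISTA proximal-gradient solver with
backtracking makes fits deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .raster import EnvStack

__all__ = ["FeatureSet", "SuitabilityModel", "SuitabilityMap",
           "build_features", "fit_maxent", "predict", "predict_points",
           "penalty_weights", "maxent_objective", "ConvergenceError"]

CLASS_ORDER = "lqpht"

# per-class penalty constants tau(class, n_presences), interpolated on n
_TAU_LQP = ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05])
_TAU_T = ([0, 100], [2.0, 1.0])


def _tau(cls: str, n: int) -> float:
    if cls in "lqp":
        return float(np.interp(n, *_TAU_LQP))
    if cls == "h":
        return 0.5
    return float(np.interp(n, *_TAU_T))


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FeatureSet:
    """Design description mapping raw predictors to the feature vector."""

    predictor_names: list[str]
    classes: str
    knots: dict[str, np.ndarray]
    feature_names: list[str]
    feature_classes: list[str]
    mins: np.ndarray   # background min per feature (for [0,1] scaling)
    maxs: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _raw(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        p = len(self.predictor_names)
        cols = []
        if "l" in self.classes:
            cols.append(X)
        if "q" in self.classes:
            cols.append(X ** 2)
        if "p" in self.classes:
            for i in range(p):
                for j in range(i + 1, p):
                    cols.append((X[:, i] * X[:, j])[:, None])
        if "h" in self.classes:
            for i, name in enumerate(self.predictor_names):
                for k in self.knots[name]:
                    cols.append(np.maximum(0.0, X[:, i] - k)[:, None])
                    cols.append(np.maximum(0.0, k - X[:, i])[:, None])
        if "t" in self.classes:
            for i, name in enumerate(self.predictor_names):
                for k in self.knots[name]:
                    cols.append((X[:, i] >= k).astype(float)[:, None])
        return np.hstack(cols)

    def transform(self, X) -> np.ndarray:
        """Feature matrix scaled to [0,1] by background statistics."""
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        raw = self._raw(np.asarray(X, float))
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return (raw - self.mins) / span


def build_features(bg_values, classes, n_knots: int = 10,
                   predictor_names: list[str] | None = None) -> FeatureSet:
    """Construct a feature set from background predictor values.

    ``classes`` is any subset of "lqpht"; hinge and threshold knots are
    placed at ``n_knots`` interior quantiles of each background predictor.
    """
    if isinstance(bg_values, pd.DataFrame):
        predictor_names = list(bg_values.columns)
        X = bg_values.to_numpy(dtype=float)
    else:
        X = np.asarray(bg_values, float)
        if predictor_names is None:
            predictor_names = [f"x{i + 1}" for i in range(X.shape[1])]
    classes = "".join(c for c in CLASS_ORDER if c in set(classes.lower()))
    if not classes:
        raise ValueError("at least one feature class is required")
    if "p" in classes and X.shape[1] < 2:
        raise ValueError("product features need at least 2 predictors")
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    knots = {name: np.unique(np.quantile(X[:, i], qs))
             for i, name in enumerate(predictor_names)}
    # enumerate feature names in the same order _raw emits them
    names, fclasses = [], []
    p = len(predictor_names)
    if "l" in classes:
        names += predictor_names
        fclasses += ["l"] * p
    if "q" in classes:
        names += [f"{n}^2" for n in predictor_names]
        fclasses += ["q"] * p
    if "p" in classes:
        for i in range(p):
            for j in range(i + 1, p):
                names.append(f"{predictor_names[i]}*{predictor_names[j]}")
                fclasses.append("p")
    if "h" in classes:
        for name in predictor_names:
            for k in knots[name]:
                names += [f"h({name}>{k:.4g})", f"h({name}<{k:.4g})"]
                fclasses += ["h", "h"]
    if "t" in classes:
        for name in predictor_names:
            for k in knots[name]:
                names.append(f"t({name}>={k:.4g})")
                fclasses.append("t")
    fs = FeatureSet(predictor_names, classes, knots, names, fclasses,
                    mins=np.zeros(len(names)), maxs=np.ones(len(names)))
    raw = fs._raw(X)
    fs.mins = raw.min(axis=0)
    fs.maxs = raw.max(axis=0)
    return fs


@dataclass
class SuitabilityModel:
    features: FeatureSet
    coefficients: np.ndarray
    rm: float
    log_partition: float        # log Z over the calibration background
    entropy: float              # of the fitted raw distribution
    calibration_range: dict[str, tuple[float, float]]
    n_iter: int = 0

    @property
    def n_parameters(self) -> int:
        """Count of nonzero coefficients (feeds AICc)."""
        return int(np.sum(self.coefficients != 0))


@dataclass
class SuitabilityMap:
    """Raster of suitabilities in [0,1]; NaN cells are masked."""

    values: np.ndarray
    stack: EnvStack             # grid frame the values live on
    output: str = "cloglog"
    provenance: dict = field(default_factory=dict)
    sd: np.ndarray | None = None

    def at_points(self, x, y) -> np.ndarray:
        row, col = self.stack.rowcol(np.asarray(x, float),
                                     np.asarray(y, float))
        ok = self.stack.inside(row, col)
        out = np.full(np.atleast_1d(row).shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out


def penalty_weights(features: FeatureSet, F_pres: np.ndarray,
                    F_bg: np.ndarray, rm: float) -> np.ndarray:
    """Per-feature L1 weights: rm * tau(class, n) * sd_j / sqrt(n)."""
    n_pres = F_pres.shape[0]
    sd = F_pres.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, F_bg.std(axis=0, ddof=0))
    sd = np.maximum(sd, 1e-3)
    tau = np.array([_tau(c, n_pres) for c in features.feature_classes])
    return rm * tau * sd / np.sqrt(n_pres)


def maxent_objective(beta: np.ndarray, F_pres: np.ndarray,
                     F_bg: np.ndarray, lam: np.ndarray) -> float:
    """Penalized negative log-likelihood the solver minimizes."""
    return float(-F_pres.mean(axis=0) @ beta + logsumexp(F_bg @ beta)
                 + np.sum(lam * np.abs(beta)))


def _objective(beta, F_pres_mean, F_bg, lam):
    scores = F_bg @ beta
    return (-F_pres_mean @ beta + logsumexp(scores)
            + np.sum(lam * np.abs(beta)))


def fit_maxent(presence_values, background_values, features: FeatureSet,
               rm: float = 1.0, tol: float = 1e-7, max_iter: int = 5000
               ) -> SuitabilityModel:
    """L1-regularized maximum-entropy fit (FISTA with backtracking).

    ``presence_values`` / ``background_values`` are (cells x predictors);
    the background defines the partition function and should already be
    restricted to the calibration region (e.g. a buffer of the
    occurrences).
    """
    if rm <= 0:
        raise ValueError("rm must be positive")
    Xp = (presence_values[features.predictor_names].to_numpy(dtype=float)
          if isinstance(presence_values, pd.DataFrame)
          else np.asarray(presence_values, float))
    Xb = (background_values[features.predictor_names].to_numpy(dtype=float)
          if isinstance(background_values, pd.DataFrame)
          else np.asarray(background_values, float))
    n_pres = Xp.shape[0]
    if n_pres < 10:
        raise ValueError("need at least 10 presences")
    F_pres = features.transform(Xp)
    F_bg = features.transform(Xb)
    fmean = F_pres.mean(axis=0)
    lam = penalty_weights(features, F_pres, F_bg, rm)

    def smooth_grad(beta):
        s = F_bg @ beta
        s -= s.max()
        w = np.exp(s)
        w /= w.sum()
        return -fmean + F_bg.T @ w

    def smooth_val(beta):
        return -fmean @ beta + logsumexp(F_bg @ beta)

    nf = features.n_features
    beta = np.zeros(nf)
    yv = beta.copy()
    t_mom = 1.0
    L = 1.0
    f_prev = _objective(beta, fmean, F_bg, lam)
    converged = False
    for it in range(1, max_iter + 1):
        g = smooth_grad(yv)
        fy = smooth_val(yv)
        while True:
            cand = yv - g / L
            cand = np.sign(cand) * np.maximum(np.abs(cand) - lam / L, 0.0)
            diff = cand - yv
            if (smooth_val(cand)
                    <= fy + g @ diff + 0.5 * L * diff @ diff + 1e-12):
                break
            L *= 2.0
            if L > 1e12:
                raise ConvergenceError("backtracking failed: L overflow")
        t_next = 0.5 * (1 + np.sqrt(1 + 4 * t_mom ** 2))
        yv = cand + (t_mom - 1) / t_next * (cand - beta)
        beta, t_mom = cand, t_next
        L *= 0.9
        f_cur = _objective(beta, fmean, F_bg, lam)
        if abs(f_prev - f_cur) <= tol * (abs(f_prev) + 1):
            converged = True
            break
        f_prev = f_cur
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(last objective change {abs(f_prev - f_cur):.3e})")
    beta = np.where(np.abs(beta) < 1e-12, 0.0, beta)
    scores = F_bg @ beta
    logz = float(logsumexp(scores))
    logp = scores - logz
    entropy = float(-np.sum(np.exp(logp) * logp))
    cal_range = {n: (float(Xb[:, i].min()), float(Xb[:, i].max()))
                 for i, n in enumerate(features.predictor_names)}
    return SuitabilityModel(features, beta, rm, logz, entropy, cal_range,
                            n_iter=it)


def _apply_extrapolation(X: np.ndarray, model: SuitabilityModel,
                         mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Returns (values usable for prediction, out-of-range mask)."""
    out = np.zeros(X.shape[0], dtype=bool)
    Xc = X.copy()
    for i, name in enumerate(model.features.predictor_names):
        lo, hi = model.calibration_range[name]
        off = (X[:, i] < lo) | (X[:, i] > hi)
        out |= off
        if mode == "clamp":
            Xc[:, i] = np.clip(X[:, i], lo, hi)
    return (Xc if mode == "clamp" else X), out


def predict(model: SuitabilityModel, stack: EnvStack,
            output: str = "cloglog", extrapolation: str = "mask"
            ) -> SuitabilityMap:
    """Project the model onto a predictor stack.

    ``raw`` output renormalizes the exponential scores over the unmasked
    prediction region (sums to 1 there); ``cloglog`` is the bounded
    transform ``1 - exp(-exp(H) * raw)`` with H the calibration entropy.
    Cells with predictors outside the calibration range are masked
    (``extrapolation="mask"``, the no-extrapolation transfer) or truncated
    to the range boundary (``"clamp"``).
    """
    if output not in ("raw", "cloglog"):
        raise ValueError("output must be 'raw' or 'cloglog'")
    if extrapolation not in ("mask", "clamp"):
        raise ValueError("extrapolation must be 'mask' or 'clamp'")
    names = model.features.predictor_names
    vals = np.stack([stack.layer(n) for n in names])
    finite = np.all(np.isfinite(vals), axis=0)
    rows, cols = np.nonzero(finite)
    X = vals[:, rows, cols].T
    X, out_of_range = _apply_extrapolation(X, model, extrapolation)
    usable = ~out_of_range if extrapolation == "mask" else np.ones(
        len(X), bool)
    grid = np.full(stack.shape, np.nan)
    if not usable.any():
        warnings.warn("all cells fall outside the calibration range; "
                      "empty suitability map", stacklevel=2)
        return SuitabilityMap(grid, stack, output)
    scores = model.features.transform(X[usable]) @ model.coefficients
    if output == "raw":
        # probabilities renormalized over the prediction region (sum to 1)
        vals_out = np.exp(scores - logsumexp(scores))
    else:
        # cloglog keeps the calibration normalization, so transferred maps
        # stay comparable regardless of the prediction region's size
        raw_cal = np.exp(scores - model.log_partition)
        vals_out = 1.0 - np.exp(-np.exp(model.entropy) * raw_cal)
    grid[rows[usable], cols[usable]] = vals_out
    frac_masked = 1.0 - usable.mean()
    if extrapolation == "mask" and frac_masked > 0.5:
        warnings.warn(f"{100 * frac_masked:.0f}% of cells masked as "
                      "out of calibration range", stacklevel=2)
    return SuitabilityMap(grid, stack, output,
                          provenance={"extrapolation": extrapolation,
                                      "masked_fraction": frac_masked})


def predict_points(model: SuitabilityModel, values,
                   output: str = "raw") -> np.ndarray:
    """Suitability at point predictor values, normalized over the
    CALIBRATION background (raw values are the per-cell probabilities the
    AICc likelihood uses)."""
    if isinstance(values, pd.DataFrame):
        values = values[model.features.predictor_names].to_numpy(float)
    X = np.asarray(values, float)
    scores = model.features.transform(X) @ model.coefficients
    raw = np.exp(scores - model.log_partition)
    if output == "raw":
        return raw
    return 1.0 - np.exp(-np.exp(model.entropy) * raw)
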