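"""Three-dimensional niche overlap.

Two complementary estimators over occurrence scores in PC space:

* convex polyhedra connecting extreme occurrences, with exact intersection
  volumes (the conservative, data-envelope view);
* Bayesian multivariate-normal niche regions — the posterior of (mean,
  covariance) under a noninformative normal–inverse-Wishart model, with
  Monte-Carlo niche-region overlap fractions and credible intervals.

Overlap is directional: the share of one niche lying inside the other's
region, reported both ways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, Delaunay, HalfspaceIntersection, QhullError

__all__ = ["ConvexNiche", "EllipsoidNiche", "OverlapPosterior",
           "hull_niche", "hull_overlap", "posterior_niche",
           "ellipsoid_overlap", "per_pc_overlaps"]


@dataclass
class ConvexNiche:
    points: np.ndarray
    hull: ConvexHull

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    @property
    def hull_vertices(self) -> np.ndarray:
        return self.points[self.hull.vertices]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class EllipsoidNiche:
    means: np.ndarray        # (n_draws, k)
    covs: np.ndarray         # (n_draws, k, k)
    n: int
    sample_mean: np.ndarray
    sample_cov: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class OverlapPosterior:
    samples: np.ndarray
    mean: float
    ci: tuple[float, float]
    alpha: float


def hull_niche(scores: np.ndarray, k: int | None = None) -> ConvexNiche:
    """Convex polyhedron connecting extreme occurrences in PC space."""
    pts = np.asarray(scores, float)
    if k is not None:
        pts = pts[:, :k]
    n, d = pts.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points in {d}-D")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError(
            f"degenerate point set (affinely dependent in {d}-D): "
            f"{str(err).splitlines()[0]}") from None
    return ConvexNiche(pts, hull)


def _chebyshev_center(halfspaces: np.ndarray):
    """Largest inscribed ball of {x : Ax + b <= 0}; (center, radius)."""
    A, b = halfspaces[:, :-1], halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    d = A.shape[1]
    c = np.zeros(d + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=np.hstack([A, norms]), b_ub=-b,
                  bounds=[(None, None)] * d + [(0, None)],
                  method="highs")
    if not res.success or res.x[-1] <= 0:
        return None, 0.0
    return res.x[:-1], float(res.x[-1])


def _mc_intersection_volume(a: ConvexNiche, b: ConvexNiche,
                            n_points: int = 1_000_000,
                            seed: int | None = 0) -> float:
    """Monte-Carlo fallback: point counting in the bounding box."""
    lo = np.maximum(a.points.min(axis=0), b.points.min(axis=0))
    hi = np.minimum(a.points.max(axis=0), b.points.max(axis=0))
    if np.any(hi <= lo):
        return 0.0
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, a.dim))
    da = Delaunay(a.hull_vertices)
    db = Delaunay(b.hull_vertices)
    inside = (da.find_simplex(pts) >= 0) & (db.find_simplex(pts) >= 0)
    return float(np.prod(hi - lo) * inside.mean())


def hull_overlap(a: ConvexNiche, b: ConvexNiche,
                 mc_fallback_points: int = 1_000_000,
                 seed: int | None = 0):
    """Directional hull containment: (pct_a_in_b, pct_b_in_a, shared_volume).

    The intersection polytope is built exactly by half-space intersection
    around a Chebyshev-center feasible point; a Monte-Carlo point count
    stands in when the exact construction is ill-conditioned.
    """
    if a.dim != b.dim:
        raise ValueError("hull dimensions differ")
    halfspaces = np.vstack([a.hull.equations, b.hull.equations])
    center, radius = _chebyshev_center(halfspaces)
    if center is None or radius < 1e-12:
        shared = 0.0
    else:
        try:
            hs = HalfspaceIntersection(halfspaces, center)
            shared = float(ConvexHull(hs.intersections).volume)
        except (QhullError, ValueError):
            shared = _mc_intersection_volume(a, b, mc_fallback_points, seed)
    return (100.0 * shared / a.volume, 100.0 * shared / b.volume, shared)


def posterior_niche(scores: np.ndarray, n_draws: int = 10_000,
                    seed: int | None = 0) -> EllipsoidNiche:
    """Posterior sample of (mean, covariance) for a multivariate-normal
    niche under the noninformative reference prior.

    covariance ~ inverse-Wishart((n-1) S, n-1);
    mean | covariance ~ normal(sample mean, covariance / n).
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} records in {k}-D")
    xbar = x.mean(axis=0)
    S = np.cov(x, rowvar=False, ddof=1).reshape(k, k)
    if np.linalg.matrix_rank(S) < k:
        raise ValueError("singular sample covariance")
    rng = np.random.default_rng(seed)
    covs = stats.invwishart.rvs(df=n - 1, scale=(n - 1) * S,
                                size=n_draws, random_state=rng)
    covs = np.asarray(covs).reshape(n_draws, k, k)
    chol = np.linalg.cholesky(covs / n)
    z = rng.standard_normal((n_draws, k))
    means = xbar + np.einsum("dij,dj->di", chol, z)
    return EllipsoidNiche(means, covs, n, xbar, S)


def ellipsoid_overlap(a: EllipsoidNiche, b: EllipsoidNiche,
                      alpha: float = 0.95, nprob: int = 1000,
                      seed: int | None = 0, cred: float = 0.95,
                      batch: int = 500) -> OverlapPosterior:
    """Posterior of the niche-region overlap of A onto B.

    For each paired posterior draw, ``nprob`` points are sampled from A's
    normal niche and the fraction falling inside B's alpha-probability
    ellipsoid (Mahalanobis distance below the chi-square quantile) is the
    overlap sample.  Returns the posterior mean and an equal-tailed
    credible interval.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if a.dim != b.dim:
        raise ValueError("niche dimensions differ")
    k = a.dim
    D = min(a.n_draws, b.n_draws)
    q = stats.chi2.ppf(alpha, df=k)
    rng = np.random.default_rng(seed)
    samples = np.empty(D)
    for start in range(0, D, batch):
        sl = slice(start, min(start + batch, D))
        m = sl.stop - sl.start
        La = np.linalg.cholesky(a.covs[sl])
        z = rng.standard_normal((m, nprob, k))
        pts = a.means[sl, None, :] + np.einsum("dij,dpj->dpi", La, z)
        diff = pts - b.means[sl, None, :]
        sol = np.linalg.solve(b.covs[sl], np.swapaxes(diff, 1, 2))
        maha = np.einsum("dpi,dip->dp", diff, sol)
        samples[sl] = (maha <= q).mean(axis=1)
    lo, hi = np.quantile(samples, [(1 - cred) / 2, 1 - (1 - cred) / 2])
    return OverlapPosterior(samples, float(samples.mean()),
                            (float(lo), float(hi)), alpha)


def per_pc_overlaps(scores_a: np.ndarray, scores_b: np.ndarray,
                    alpha: float = 0.95, n_draws: int = 10_000,
                    nprob: int = 1000, seed: int | None = 0
                    ) -> dict[str, OverlapPosterior]:
    """One-dimensional niche-region overlaps per PC axis (A onto B)."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    out = {}
    for j in range(scores_a.shape[1]):
        pa = posterior_niche(scores_a[:, [j]], n_draws, seed=seed)
        pb = posterior_niche(scores_b[:, [j]], n_draws,
                             seed=None if seed is None else seed + 1)
        out[f"pc{j + 1}"] = ellipsoid_overlap(pa, pb, alpha, nprob,
                                              seed=seed)
    return out
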