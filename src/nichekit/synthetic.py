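"""Virtual landscapes and virtual species with known Gaussian climatic
niches.

The generator provides every downstream stage with inputs whose answers
are analytically known: autocorrelated multi-layer environments, two-range
occurrence samples drawn from a specified niche, perturbed "paleo"
variants of a stack, and closed-form / Monte-Carlo niche-overlap oracles.

Landscapes are smoothed Gaussian noise: independent white-noise fields are
kernel-smoothed (the smoothing sd sets the autocorrelation range),
re-standardized, and mixed by the Cholesky factor of the requested
inter-layer correlation matrix.  Only the statistical structure of real
climate grids is emulated, not their physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .prep import OccurrenceSet
from .raster import EnvStack

__all__ = [
    "VirtualSpecies", "LandscapeSpec", "make_landscape",
    "sample_occurrences", "make_paleo_stack", "analytic_overlap",
    "analytic_density_overlap", "suitability",
]


@dataclass
class VirtualSpecies:
    """A Gaussian climatic niche in environment units.

    Suitability at environment ``x`` is ``exp(-0.5 (x-mu)' Sigma^-1 (x-mu))``
    times ``detection_scale``.
    """

    niche_mean: np.ndarray
    niche_cov: np.ndarray
    detection_scale: float = 1.0
    label: str = "virtual"
    layer_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.niche_mean = np.atleast_1d(np.asarray(self.niche_mean, float))
        self.niche_cov = np.atleast_2d(np.asarray(self.niche_cov, float))
        k = self.niche_mean.size
        if self.niche_cov.shape != (k, k):
            raise ValueError("niche_cov shape does not match niche_mean")
        if not np.allclose(self.niche_cov, self.niche_cov.T):
            raise ValueError("niche_cov must be symmetric")
        try:
            np.linalg.cholesky(self.niche_cov)
        except np.linalg.LinAlgError:
            raise ValueError("niche_cov must be positive definite") from None
        if not 0 < self.detection_scale <= 1:
            raise ValueError("detection_scale must be in (0, 1]")

    @property
    def dim(self) -> int:
        return self.niche_mean.size


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic multi-layer environment."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    n_layers: int = 3
    autocorr_range: float = 10.0
    inter_layer_corr: np.ndarray | None = None
    seed: int = 0
    layer_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("grid must be at least 10 x 10")
        if self.autocorr_range <= 0:
            raise ValueError("autocorr_range must be positive")
        if self.inter_layer_corr is None:
            self.inter_layer_corr = np.eye(self.n_layers)
        self.inter_layer_corr = np.asarray(self.inter_layer_corr, float)
        if self.inter_layer_corr.shape != (self.n_layers, self.n_layers):
            raise ValueError("inter_layer_corr has wrong shape")
        if not np.allclose(self.inter_layer_corr, self.inter_layer_corr.T):
            raise ValueError("inter_layer_corr must be symmetric")
        if not np.allclose(np.diag(self.inter_layer_corr), 1.0):
            raise ValueError("inter_layer_corr diagonal must be 1")
        try:
            np.linalg.cholesky(self.inter_layer_corr)
        except np.linalg.LinAlgError:
            raise ValueError(
                "inter_layer_corr must be positive definite") from None
        if self.layer_names is None:
            self.layer_names = [f"env{i + 1}" for i in range(self.n_layers)]


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float
                  ) -> np.ndarray:
    """Standardized kernel-smoothed white noise."""
    z = rng.standard_normal(shape)
    if sigma_cells > 1e-9:
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def make_landscape(spec: LandscapeSpec) -> EnvStack:
    """Generate an autocorrelated, inter-correlated layer stack.

    Deterministic given ``spec.seed``.  Each layer has mean ~0 and sd ~1;
    sample inter-layer correlations approximate ``spec.inter_layer_corr``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = spec.autocorr_range / spec.cell_size
    fields = np.stack([
        _smooth_field(rng, (spec.n_rows, spec.n_cols), sigma)
        for _ in range(spec.n_layers)
    ])
    chol = np.linalg.cholesky(spec.inter_layer_corr)
    mixed = np.einsum("ij,jrc->irc", chol, fields)
    return EnvStack(list(spec.layer_names), mixed,
                    x0=0.0, y0=spec.n_rows * spec.cell_size,
                    cell_size=spec.cell_size, crs="projected")


def suitability(sp: VirtualSpecies, stack: EnvStack) -> np.ndarray:
    """Gaussian suitability surface of a species over a stack (0..1)."""
    names = sp.layer_names or stack.layer_names[:sp.dim]
    vals = np.stack([stack.layer(n) for n in names])  # (k, r, c)
    diff = vals - sp.niche_mean[:, None, None]
    prec = np.linalg.inv(sp.niche_cov)
    maha = np.einsum("irc,ij,jrc->rc", diff, prec, diff)
    return sp.detection_scale * np.exp(-0.5 * maha)


def sample_occurrences(sp: VirtualSpecies, stack: EnvStack, n: int,
                       region_mask: np.ndarray | None = None,
                       seed: int | None = 0,
                       range_label: str = "west",
                       variety_label: str = "typical") -> OccurrenceSet:
    """Draw ``n`` distinct cells with probability proportional to niche
    suitability inside ``region_mask``; records sit at cell centers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = suitability(sp, stack)
    ok = np.isfinite(suit) & (suit > 0)
    if region_mask is not None:
        if region_mask.shape != stack.shape:
            raise ValueError("region_mask shape mismatch")
        ok &= region_mask.astype(bool)
    rows, cols = np.nonzero(ok)
    w = suit[rows, cols]
    if rows.size < n:
        raise ValueError(
            f"mask holds only {rows.size} positive-suitability cells, "
            f"need {n}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False, p=w / w.sum())
    x, y = stack.xy(rows[pick], cols[pick])
    return OccurrenceSet.from_xy(np.column_stack([x, y]), range_label,
                                 variety_label, crs=stack.crs)


def make_paleo_stack(stack: EnvStack, shift, smooth_noise_sd=0.0,
                     autocorr_range: float | None = None,
                     seed: int | None = 0) -> EnvStack:
    """Perturbed scenario stack: layer i = original + shift_i + smooth noise.

    Emulates an alternative-period climate sharing the grid of the current
    one.  Noise is autocorrelated with the given range (default: 5 cells).
    """
    shift = np.atleast_1d(np.asarray(shift, float))
    if shift.size != stack.n_layers:
        raise ValueError("shift length must equal the number of layers")
    sd = np.broadcast_to(np.atleast_1d(np.asarray(smooth_noise_sd, float)),
                         (stack.n_layers,))
    rng = np.random.default_rng(seed)
    sigma = (autocorr_range if autocorr_range is not None
             else 5 * stack.cell_size) / stack.cell_size
    out = stack.data.copy()
    for i in range(stack.n_layers):
        out[i] += shift[i]
        if sd[i] > 0:
            out[i] += sd[i] * _smooth_field(rng, stack.shape, sigma)
    return EnvStack(list(stack.layer_names), out, stack.x0, stack.y0,
                    stack.cell_size, stack.crs)


def analytic_overlap(a: VirtualSpecies, b: VirtualSpecies, alpha: float,
                     n_mc: int = 1_000_000, seed: int | None = 0) -> float:
    """Ground-truth niche-region overlap.

    P[X ~ N(mu_a, Sigma_a) falls inside the alpha-probability ellipsoid of
    N(mu_b, Sigma_b)]; closed form (normal CDF) in 1-D, Monte Carlo with
    ``n_mc`` draws otherwise.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if a.dim != b.dim:
        raise ValueError("species dimensions differ")
    k = a.dim
    q = stats.chi2.ppf(alpha, df=k)
    if k == 1:
        mu_a, sd_a = a.niche_mean[0], np.sqrt(a.niche_cov[0, 0])
        mu_b, sd_b = b.niche_mean[0], np.sqrt(b.niche_cov[0, 0])
        c = np.sqrt(q) * sd_b
        return float(stats.norm.cdf((mu_b + c - mu_a) / sd_a)
                     - stats.norm.cdf((mu_b - c - mu_a) / sd_a))
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(a.niche_mean, a.niche_cov, size=n_mc,
                                method="cholesky")
    diff = x - b.niche_mean
    sol = np.linalg.solve(b.niche_cov, diff.T)
    maha = np.einsum("ij,ji->i", diff, sol)
    return float(np.mean(maha <= q))


def analytic_density_overlap(a: VirtualSpecies, b: VirtualSpecies,
                             n_grid: int = 400, pad_sd: float = 6.0
                             ) -> float:
    """Brute-force Schoener's-D-style density overlap of two Gaussian
    niches: 1 - 0.5 * integral |f_a - f_b|, by quadrature on a fine grid.

    Supports 1-D and 2-D niches (the E-space dimensions used by the 2-D
    grid analysis).
    """
    if a.dim != b.dim:
        raise ValueError("species dimensions differ")
    k = a.dim
    sds_a = np.sqrt(np.diag(a.niche_cov))
    sds_b = np.sqrt(np.diag(b.niche_cov))
    lo = np.minimum(a.niche_mean - pad_sd * sds_a,
                    b.niche_mean - pad_sd * sds_b)
    hi = np.maximum(a.niche_mean + pad_sd * sds_a,
                    b.niche_mean + pad_sd * sds_b)
    axes = [np.linspace(lo[i], hi[i], n_grid) for i in range(k)]
    if k == 1:
        pts = axes[0][:, None]
        dvol = axes[0][1] - axes[0][0]
    elif k == 2:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        dvol = (axes[0][1] - axes[0][0]) * (axes[1][1] - axes[1][0])
    else:
        raise ValueError("density overlap quadrature supports k <= 2")
    fa = stats.multivariate_normal.pdf(pts, a.niche_mean, a.niche_cov)
    fb = stats.multivariate_normal.pdf(pts, b.niche_mean, b.niche_cov)
    return float(1.0 - 0.5 * np.sum(np.abs(fa - fb)) * dvol)
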