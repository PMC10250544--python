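"""Environmental space (E-space): PCA over background climates, projection
of occurrences and rasters onto the components, and the gridded
kernel-density occupancy surfaces used by the 2-D overlap statistics.

The PCA is calibrated on pooled background cells, standardized per layer
(a PCA of the background correlation matrix).  Occupancy grids follow the
occurrence-density framework of PCA-env analyses: Gaussian kernel
densities of occurrences (``o``) and of the background (``e``) on an
R x R grid, an availability-corrected occupancy ``z = (o/e)/max(o/e)``
and its normalization ``Z`` (sums to one), on which Schoener's D and the
niche-dynamics indices operate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import PCA

from .raster import EnvStack

__all__ = ["EspaceModel", "OccupancyGrid", "fit_pca", "project",
           "project_stack", "reconstruct", "occupancy_grid",
           "silverman_bandwidth", "pooled_axis_ranges"]


@dataclass
class EspaceModel:
    """Standardize-then-rotate model of the background climate."""

    layer_names: list[str]
    center: np.ndarray            # per-layer mean
    scale: np.ndarray             # per-layer sd
    loadings: np.ndarray          # layers x components, orthonormal columns
    explained: np.ndarray         # variance fraction per component

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(stacks, masks=None, n_components: int | None = None
            ) -> EspaceModel:
    """PCA of pooled background cells, standardized per layer.

    ``stacks`` is one EnvStack or a sequence sharing layer names; ``masks``
    optionally restricts each stack to its background cells.  Components
    are ordered by decreasing explained variance; the largest-magnitude
    loading of each component is made positive.
    """
    if isinstance(stacks, EnvStack):
        stacks = [stacks]
    if masks is None:
        masks = [None] * len(stacks)
    names = stacks[0].layer_names
    tables = []
    for st, m in zip(stacks, masks):
        if st.layer_names != names:
            raise ValueError("stacks have mismatched layer names")
        tables.append(st.table(m))
    pooled = pd.concat(tables, ignore_index=True).to_numpy()
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 layers")
    if pooled.shape[0] <= pooled.shape[1]:
        raise ValueError("fewer pooled background cells than layers")
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0, ddof=1)
    for nm, s in zip(names, scale):
        if s == 0:
            raise ValueError(f"layer {nm!r} is constant over the background")
    zs = (pooled - center) / scale
    pca = PCA(n_components=n_components or pooled.shape[1])
    pca.fit(zs)
    loadings = pca.components_.T.copy()     # layers x comps
    # sign convention: dominant loading positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return EspaceModel(list(names), center, scale, loadings,
                       pca.explained_variance_ratio_.copy())


def project(model: EspaceModel, values: pd.DataFrame,
            n_components: int | None = None) -> np.ndarray:
    """Score table (points x components) for raw layer values."""
    missing = [n for n in model.layer_names if n not in values.columns]
    if missing:
        raise ValueError(f"missing layers {missing}")
    x = values[model.layer_names].to_numpy(dtype=float)
    zs = (x - model.center) / model.scale
    scores = zs @ model.loadings
    return scores[:, :n_components] if n_components else scores


def project_stack(model: EspaceModel, stack: EnvStack,
                  n_components: int | None = None) -> EnvStack:
    """PC-layer stack (used downstream as SDM predictors)."""
    k = n_components or model.n_components
    vals = np.stack([stack.layer(n) for n in model.layer_names])
    zs = (vals - model.center[:, None, None]) / model.scale[:, None, None]
    pcs = np.einsum("lrc,lk->krc", zs, model.loadings[:, :k])
    names = [f"pc{i + 1}" for i in range(k)]
    return EnvStack(names, pcs, stack.x0, stack.y0, stack.cell_size,
                    stack.crs)


def reconstruct(model: EspaceModel, scores: np.ndarray) -> pd.DataFrame:
    """Back-transform component scores to raw layer units (exact when all
    components are kept)."""
    scores = np.asarray(scores, float)
    zs = scores @ model.loadings[:, :scores.shape[1]].T
    return pd.DataFrame(zs * model.scale + model.center,
                        columns=model.layer_names)


@dataclass
class OccupancyGrid:
    """R x R E-space grid of occurrence density, availability and occupancy."""

    R: int
    axis_ranges: tuple[tuple[float, float], tuple[float, float]]
    o: np.ndarray      # occurrence density
    e: np.ndarray      # background (availability) density
    z: np.ndarray      # corrected occupancy in [0, 1]
    Z: np.ndarray      # z normalized to sum 1
    bandwidth: tuple[float, float]
    support: np.ndarray | None = None  # cells holding background points

    def __post_init__(self) -> None:
        if self.support is None:
            self.support = self.e > 0

    def same_frame(self, other: "OccupancyGrid") -> bool:
        return (self.R == other.R
                and np.allclose(self.axis_ranges, other.axis_ranges))


def silverman_bandwidth(scores: np.ndarray) -> np.ndarray:
    """Normal-reference bandwidth per axis for 2-D data: sd * n^(-1/6)."""
    scores = np.asarray(scores, float)
    n, d = scores.shape
    sd = scores.std(axis=0, ddof=1)
    return sd * n ** (-1.0 / (d + 4))


def pooled_axis_ranges(*score_sets, pad: float = 0.05):
    """Shared axis ranges: pooled min/max per PC plus a margin."""
    pooled = np.vstack(score_sets)
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    span = hi - lo
    return tuple((float(lo[i] - pad * span[i]), float(hi[i] + pad * span[i]))
                 for i in range(pooled.shape[1]))


def _kde_on_grid(pts: np.ndarray, centers_x: np.ndarray,
                 centers_y: np.ndarray, bw: np.ndarray) -> np.ndarray:
    """Diagonal-bandwidth Gaussian KDE at grid cell centers (separable)."""
    kx = np.exp(-0.5 * ((pts[:, 0:1] - centers_x[None, :]) / bw[0]) ** 2)
    ky = np.exp(-0.5 * ((pts[:, 1:2] - centers_y[None, :]) / bw[1]) ** 2)
    dens = kx.T @ ky  # (Rx, Ry)
    return dens / (len(pts) * 2 * np.pi * bw[0] * bw[1])


def occupancy_grid(scores_occ: np.ndarray, scores_bg: np.ndarray,
                   R: int = 100, bandwidth=None, axis_ranges=None,
                   corrected: bool = True) -> OccupancyGrid:
    """Kernel occupancy surfaces on an R x R grid over the first two PCs.

    ``axis_ranges`` should be shared between the grids being compared
    (computed from the pooled backgrounds); by default it is the envelope
    of ``scores_bg`` plus 5%.  ``corrected=True`` divides occurrence
    density by availability before normalizing (the recommended variant);
    ``corrected=False`` uses ``z = o / max(o)``.
    """
    scores_occ = np.asarray(scores_occ, float)[:, :2]
    scores_bg = np.asarray(scores_bg, float)[:, :2]
    if R < 10:
        raise ValueError("R must be at least 10")
    if len(scores_occ) < 5:
        raise ValueError("need at least 5 occurrence scores")
    if bandwidth is None:
        bw = silverman_bandwidth(scores_occ)
    else:
        bw = np.broadcast_to(np.atleast_1d(np.asarray(bandwidth, float)),
                             (2,)).copy()
    if np.any(bw <= 0):
        raise ValueError("singular bandwidth")
    if axis_ranges is None:
        axis_ranges = pooled_axis_ranges(scores_bg)
    (x0, x1), (y0, y1) = axis_ranges
    cx = x0 + (np.arange(R) + 0.5) * (x1 - x0) / R
    cy = y0 + (np.arange(R) + 0.5) * (y1 - y0) / R
    o = _kde_on_grid(scores_occ, cx, cy, bw)
    bw_bg = silverman_bandwidth(scores_bg) if bandwidth is None else bw
    e = _kde_on_grid(scores_bg, cx, cy, bw_bg)
    # availability support: the cells that actually hold background points,
    # with single-cell sampling holes closed (keeps the o/e correction from
    # exploding in KDE tails where no environment exists)
    hist, _, _ = np.histogram2d(scores_bg[:, 0], scores_bg[:, 1],
                                bins=R, range=[(x0, x1), (y0, y1)])
    support = ndimage.binary_closing(hist > 0, structure=np.ones((3, 3)))
    if corrected:
        ratio = np.zeros_like(o)
        ratio[support] = o[support] / e[support]
    else:
        ratio = np.where(support, o, 0.0)
    m = ratio.max()
    z = ratio / m if m > 0 else ratio
    total = z.sum()
    if total <= 0:
        raise ValueError("empty occupancy: no occurrence mass on the grid")
    return OccupancyGrid(R, tuple(axis_ranges), o, e, z, z / total,
                         (float(bw[0]), float(bw[1])), support)
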