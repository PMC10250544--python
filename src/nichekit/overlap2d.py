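"""Two-dimensional niche comparison: Schoener's D, equivalency and
similarity randomization tests (with divergence and conservatism
alternatives), and the expansion / stability / unfilling niche-dynamics
indices.

All statistics operate on :class:`~nichekit.espace.OccupancyGrid` surfaces
sharing one grid frame.  The tests take PC score arrays (occurrences and
backgrounds already projected into E-space) and rebuild occupancy grids
per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .espace import OccupancyGrid, occupancy_grid, pooled_axis_ranges

__all__ = ["OverlapTestResult", "NicheDynamics", "schoener_D",
           "equivalency_test", "similarity_test", "niche_dynamics"]


@dataclass
class OverlapTestResult:
    D_observed: float
    null_D: np.ndarray
    p_divergence: float
    p_conservatism: float
    n_reps: int
    direction: tuple[str, str] = ("A", "B")


@dataclass
class NicheDynamics:
    expansion: float
    stability: float
    unfilling: float
    analogue_restricted: bool = True


def schoener_D(g1: OccupancyGrid, g2: OccupancyGrid) -> float:
    """D = 1 - 0.5 * sum |Z1 - Z2|; 0 = disjoint, 1 = identical niches."""
    if not g1.same_frame(g2):
        raise ValueError("occupancy grids do not share a frame")
    return float(1.0 - 0.5 * np.abs(g1.Z - g2.Z).sum())


def _pvalues(d_obs: float, null: np.ndarray) -> tuple[float, float]:
    """One-sided p-values with the +1 correction; ties count as extreme."""
    reps = null.size
    p_div = (np.sum(null <= d_obs) + 1) / (reps + 1)
    p_con = (np.sum(null >= d_obs) + 1) / (reps + 1)
    return float(p_div), float(p_con)


def equivalency_test(occ1: np.ndarray, occ2: np.ndarray,
                     bg1: np.ndarray, bg2: np.ndarray,
                     R: int = 100, reps: int = 100,
                     seed: int | None = 0, bandwidth=None,
                     corrected: bool = True) -> OverlapTestResult:
    """Niche-equivalency randomization test.

    The null pools both occurrence score sets and re-splits them at random
    into groups of the original sizes, rebuilding the occupancy grids and
    recomputing D each time.  Small p_divergence: niches are less
    equivalent than interchangeable samples would be.
    """
    occ1, occ2 = np.asarray(occ1, float), np.asarray(occ2, float)
    if reps < 19:
        raise ValueError("reps must be at least 19")
    if len(occ1) < 5 or len(occ2) < 5:
        raise ValueError("each occurrence set needs at least 5 records")
    ranges = pooled_axis_ranges(np.vstack([bg1, bg2])[:, :2])
    kw = dict(R=R, bandwidth=bandwidth, axis_ranges=ranges,
              corrected=corrected)
    g1 = occupancy_grid(occ1, bg1, **kw)
    g2 = occupancy_grid(occ2, bg2, **kw)
    d_obs = schoener_D(g1, g2)
    pooled = np.vstack([occ1[:, :2], occ2[:, :2]])
    n1 = len(occ1)
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(len(pooled))
        s1, s2 = pooled[perm[:n1]], pooled[perm[n1:]]
        null[r] = schoener_D(occupancy_grid(s1, bg1, **kw),
                             occupancy_grid(s2, bg2, **kw))
    p_div, p_con = _pvalues(d_obs, null)
    return OverlapTestResult(d_obs, null, p_div, p_con, reps)


def similarity_test(occ1: np.ndarray, occ2: np.ndarray,
                    bg1: np.ndarray, bg2: np.ndarray,
                    R: int = 100, reps: int = 100,
                    seed: int | None = 0, bandwidth=None,
                    corrected: bool = True,
                    max_off_support: float = 0.5) -> OverlapTestResult:
    """Niche-similarity (background) randomization test.

    The null translates range 2's observed occupancy surface to random
    positions within its background envelope (toroidal integer-cell
    shifts); shifts that move more than ``max_off_support`` of the
    occupancy mass off the background support are rejected and redrawn.
    Small p_conservatism: overlap is higher than random placement in the
    available environment would produce (niche conservatism).
    """
    if reps < 19:
        raise ValueError("reps must be at least 19")
    ranges = pooled_axis_ranges(np.vstack([bg1, bg2])[:, :2])
    kw = dict(R=R, bandwidth=bandwidth, axis_ranges=ranges,
              corrected=corrected)
    g1 = occupancy_grid(occ1, bg1, **kw)
    g2 = occupancy_grid(occ2, bg2, **kw)
    d_obs = schoener_D(g1, g2)
    support2 = g2.support
    if support2.sum() < 4:
        raise ValueError("background support too small to translate within")
    rows = np.nonzero(support2.any(axis=1))[0]
    cols = np.nonzero(support2.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1   # bounding box of the bg envelope
    c0, c1 = cols[0], cols[-1] + 1
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        for _ in range(1000):
            dx = rng.integers(0, r1 - r0)
            dy = rng.integers(0, c1 - c0)
            z_shift = np.zeros_like(g2.z)
            z_shift[r0:r1, c0:c1] = np.roll(
                np.roll(g2.z[r0:r1, c0:c1], dx, axis=0), dy, axis=1)
            mass_on = z_shift[support2].sum()
            total = z_shift.sum()
            if total > 0 and mass_on / total >= 1.0 - max_off_support:
                break
        else:
            raise ValueError("could not find an admissible translation")
        zs = np.where(support2, z_shift, 0.0)
        g_null = OccupancyGrid(g2.R, g2.axis_ranges, g2.o, g2.e, zs,
                               zs / zs.sum(), g2.bandwidth)
        null[r] = schoener_D(g1, g_null)
    p_div, p_con = _pvalues(d_obs, null)
    return OverlapTestResult(d_obs, null, p_div, p_con, reps)


def _occupied(z: np.ndarray, marginal_quantile: float) -> np.ndarray:
    """Cells holding the top (1 - marginal_quantile) share of occupancy
    mass; the marginal density tail is not counted as niche use."""
    occupied = z > 0
    if marginal_quantile <= 0:
        return occupied
    vals = np.sort(z[occupied])[::-1]
    cum = np.cumsum(vals) / vals.sum()
    k = int(np.searchsorted(cum, 1.0 - marginal_quantile)) + 1
    thr = vals[min(k, vals.size) - 1]
    return z >= thr


def niche_dynamics(gA: OccupancyGrid, gB: OccupancyGrid,
                   analogue_only: bool = True,
                   marginal_quantile: float = 0.05) -> NicheDynamics:
    """Expansion / stability / unfilling between a source range A and a
    target range B.

    expansion  = occupancy of B in cells unused by A (share of B's total);
    stability  = 1 - expansion;
    unfilling  = occupancy of A in cells unused by B (share of A's total).
    With ``analogue_only`` the indices are computed over cells whose
    environment exists in both backgrounds.  A range's used cells are
    those carrying the top ``1 - marginal_quantile`` of its occupancy
    mass (kernel-density tails do not count as niche use).
    """
    if not gA.same_frame(gB):
        raise ValueError("occupancy grids do not share a frame")
    if gA.z.max() <= 0 or gB.z.max() <= 0:
        raise ValueError("empty occupancy grid")
    in_a = _occupied(gA.z, marginal_quantile)
    in_b = _occupied(gB.z, marginal_quantile)
    if analogue_only:
        analogue = gA.support & gB.support
        in_a &= analogue
        in_b &= analogue
    tot_b = gB.z[in_b].sum()
    tot_a = gA.z[in_a].sum()
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("empty occupancy within the analogue environment")
    expansion = gB.z[in_b & ~in_a].sum() / tot_b
    unfilling = gA.z[in_a & ~in_b].sum() / tot_a
    return NicheDynamics(float(expansion), float(1.0 - expansion),
                         float(unfilling), analogue_only)
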