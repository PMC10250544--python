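"""Occurrence cleaning: per-cell deduplication, minimum-distance spatial
thinning, random-point extraction from polygons, and per-variable Welch
comparison of the climates of two ranges.

Distances are Euclidean in map units for projected coordinates and
great-circle (haversine, R = 6371 km) for geographic ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import EnvStack

__all__ = [
    "OccurrenceSet", "dedupe_per_cell", "thin_min_distance",
    "sample_polygon_points", "welch_compare", "pairwise_distances",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

COLUMNS = ["id", "x", "y", "range_label", "variety_label"]


@dataclass
class OccurrenceSet:
    """Occurrence records: id, x, y, range label, variety label."""

    df: pd.DataFrame
    crs: str = "projected"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if len(self.df) and not np.all(np.isfinite(self.df[["x", "y"]])):
            raise ValueError("non-finite coordinates in occurrence set")

    @classmethod
    def from_xy(cls, xy: np.ndarray, range_label: str = "west",
                variety_label: str = "typical", crs: str = "projected",
                start_id: int = 0) -> "OccurrenceSet":
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        df = pd.DataFrame({
            "id": np.arange(start_id, start_id + len(xy)),
            "x": xy[:, 0], "y": xy[:, 1],
            "range_label": range_label, "variety_label": variety_label,
        })
        return cls(df, crs=crs)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def subset(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.df.iloc[np.asarray(idx)], crs=self.crs)

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        if other.crs != self.crs:
            raise ValueError("cannot concatenate occurrence sets across CRS")
        return OccurrenceSet(pd.concat([self.df, other.df],
                                       ignore_index=True), crs=self.crs)

    def write(self, path: str, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str, sep: str = ",",
             crs: str = "projected") -> "OccurrenceSet":
        return cls(pd.read_csv(path, sep=sep), crs=crs)


def pairwise_distances(xy: np.ndarray, crs: str = "projected") -> np.ndarray:
    """Symmetric distance matrix; haversine km when crs is geographic."""
    xy = np.asarray(xy, dtype=float)
    if crs == "geographic":
        lon = np.radians(xy[:, 0])[:, None]
        lat = np.radians(xy[:, 1])[:, None]
        dlon = lon - lon.T
        dlat = lat - lat.T
        a = (np.sin(dlat / 2) ** 2
             + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2)
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def dedupe_per_cell(occ: OccurrenceSet, stack: EnvStack) -> OccurrenceSet:
    """Keep at most one record per raster cell (first by input order).

    Records falling outside the stack are dropped with a logged count.
    """
    if len(occ) == 0:
        return occ
    row, col = stack.rowcol(occ.df["x"].to_numpy(), occ.df["y"].to_numpy())
    on_grid = stack.inside(row, col)
    n_off = int((~on_grid).sum())
    if n_off:
        logger.info("dedupe_per_cell: dropped %d record(s) outside the grid",
                    n_off)
    df = occ.df[on_grid].copy()
    key = pd.MultiIndex.from_arrays([row[on_grid], col[on_grid]])
    keep = ~key.duplicated(keep="first")
    return OccurrenceSet(df[keep], crs=occ.crs)


def _greedy_thin(dist: np.ndarray, dmin: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One randomized greedy pass; returns indices of retained records."""
    n = dist.shape[0]
    alive = np.ones(n, dtype=bool)
    conflict = (dist < dmin)
    np.fill_diagonal(conflict, False)
    while True:
        sub = conflict[np.ix_(alive, alive)]
        if not sub.any():
            break
        idx_alive = np.nonzero(alive)[0]
        d_alive = dist[np.ix_(alive, alive)]
        d_alive = np.where(sub, d_alive, np.inf)
        # the closest conflicting pair; drop its member with most conflicts
        i, j = np.unravel_index(np.argmin(d_alive), d_alive.shape)
        counts = sub.sum(axis=1)
        if counts[i] > counts[j]:
            drop = i
        elif counts[j] > counts[i]:
            drop = j
        else:
            drop = i if rng.random() < 0.5 else j
        alive[idx_alive[drop]] = False
    return np.nonzero(alive)[0]


def thin_min_distance(occ: OccurrenceSet, dmin: float, trials: int = 10,
                      seed: int | None = 0) -> OccurrenceSet:
    """Spatial thinning to a minimum pairwise distance.

    Runs ``trials`` randomized greedy passes, each repeatedly deleting one
    member of the closest conflicting pair (the one with more conflicts),
    and returns a pass retaining the maximum number of records.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    if len(occ) < 2:
        return occ
    dist = pairwise_distances(occ.xy, occ.crs)
    if (dist[np.triu_indices(len(occ), k=1)] >= dmin).all():
        return occ
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(max(1, trials)):
        kept = _greedy_thin(dist, dmin, rng)
        if best is None or kept.size > best.size:
            best = kept
    return occ.subset(np.sort(best))


def sample_polygon_points(polygon, n: int, dmin: float,
                          seed: int | None = 0,
                          crs: str = "projected",
                          range_label: str = "west",
                          variety_label: str = "typical",
                          max_tries_per_point: int = 200) -> OccurrenceSet:
    """Rejection-sample up to ``n`` points inside planar polygon(s),
    keeping every accepted pair at least ``dmin`` apart.

    Warns (rather than fails) when the retry budget cannot place all n.
    """
    from shapely.geometry import Point
    from shapely.ops import unary_union

    poly = unary_union(polygon) if isinstance(polygon, (list, tuple)) else polygon
    if poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate polygon: zero area")
    minx, miny, maxx, maxy = poly.bounds
    rng = np.random.default_rng(seed)
    accepted: list[tuple[float, float]] = []
    budget = max_tries_per_point * n
    while len(accepted) < n and budget > 0:
        budget -= 1
        p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if not poly.contains(Point(p)):
            continue
        if accepted:
            d = pairwise_distances(
                np.vstack([accepted, [p]]), crs)[-1, :-1]
            if (d < dmin).any():
                continue
        accepted.append(p)
    if len(accepted) < n:
        warnings.warn(
            f"sample_polygon_points: placed {len(accepted)} of {n} points "
            f"at dmin={dmin}", stacklevel=2)
    return OccurrenceSet.from_xy(np.asarray(accepted), range_label,
                                 variety_label, crs=crs)


def welch_compare(occ_a: OccurrenceSet, occ_b: OccurrenceSet,
                  stack: EnvStack, bonferroni: bool = False) -> pd.DataFrame:
    """Per-layer two-sided Welch's t-test of range climates.

    Returns a table with group means, t, Satterthwaite df and p per layer.
    Layers with zero variance in both groups get NaN statistics and a
    ``degenerate`` flag.
    """
    va = stack.extract(occ_a.df["x"].to_numpy(), occ_a.df["y"].to_numpy())
    vb = stack.extract(occ_b.df["x"].to_numpy(), occ_b.df["y"].to_numpy())
    rows = []
    for name in stack.layer_names:
        a = va[name].dropna().to_numpy()
        b = vb[name].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(f"fewer than 2 usable records on layer {name}")
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate:
            t = df_ = p = np.nan
            if np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p, df_ = res.statistic, res.pvalue, res.df
        rows.append({"layer": name, "mean_a": a.mean(), "mean_b": b.mean(),
                     "t": t, "df": df_, "p": p, "degenerate": degenerate})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out
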