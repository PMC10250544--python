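"""Multi-layer raster grids (the G-space).

An :class:`EnvStack` holds named 2-D layers that share one geotransform:
cell ``(row, col)`` has its center at ``(x0 + (col + 0.5) * cell_size,
y0 - (row + 0.5) * cell_size)``, i.e. row 0 is the northern edge.  NaN
cells are nodata.  Coordinates are planar map units by default; a
``crs="geographic"`` tag switches distance computations downstream to
great circles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnvStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class EnvStack:
    """Named stack of co-registered single-band rasters."""

    layer_names: list[str]
    data: np.ndarray  # (n_layers, n_rows, n_cols)
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    crs: str = "projected"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (layers, rows, cols)")
        if len(self.layer_names) != self.data.shape[0]:
            raise ValueError("layer_names length does not match data")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.data[self.layer_names.index(name)]
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None

    # ---- geometry -------------------------------------------------------

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices containing planar points (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        return row, col

    def xy(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates for indices (vectorized)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def inside(self, row, col) -> np.ndarray:
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    # ---- extraction -----------------------------------------------------

    def extract(self, x, y) -> pd.DataFrame:
        """Layer values at point locations; NaN outside the grid."""
        row, col = self.rowcol(x, y)
        ok = self.inside(row, col)
        out = np.full((row.size if row.ndim else 1, self.n_layers), np.nan)
        r = np.atleast_1d(row)[np.atleast_1d(ok)]
        c = np.atleast_1d(col)[np.atleast_1d(ok)]
        vals = self.data[:, r, c].T
        out[np.atleast_1d(ok)] = vals
        return pd.DataFrame(out, columns=self.layer_names)

    def table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """All finite cells as a (cells x layers) frame.

        ``mask``, if given, is a boolean (rows, cols) array restricting the
        cells (a background definition).
        """
        finite = np.all(np.isfinite(self.data), axis=0)
        if mask is not None:
            if mask.shape != self.shape:
                raise ValueError("mask shape mismatch")
            finite &= mask.astype(bool)
        vals = self.data[:, finite].T
        return pd.DataFrame(vals, columns=self.layer_names)

    def cell_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        finite = np.all(np.isfinite(self.data), axis=0)
        if mask is not None:
            finite &= mask.astype(bool)
        rows, cols = np.nonzero(finite)
        x, y = self.xy(rows, cols)
        return np.column_stack([x, y])

    def copy(self) -> "EnvStack":
        return EnvStack(list(self.layer_names), self.data.copy(),
                        self.x0, self.y0, self.cell_size, self.crs)

    # ---- I/O ------------------------------------------------------------

    def write(self, directory: str) -> list[str]:
        """Write one ESRI ASCII grid per layer; returns file paths."""
        os.makedirs(directory, exist_ok=True)
        paths = []
        for name, band in zip(self.layer_names, self.data):
            path = os.path.join(directory, f"{name}.asc")
            write_ascii_grid(path, band, self.x0,
                             self.y0 - self.shape[0] * self.cell_size,
                             self.cell_size)
            paths.append(path)
        return paths

    @classmethod
    def read(cls, paths: list[str], names: list[str] | None = None,
             crs: str = "projected") -> "EnvStack":
        """Assemble a stack from single-band ASCII grids."""
        bands, meta = [], None
        for p in paths:
            band, m = read_ascii_grid(p)
            if meta is None:
                meta = m
            elif m != meta:
                raise ValueError(f"{p} does not share the stack geotransform")
            bands.append(band)
        if names is None:
            names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
        xll, yll, cs = meta
        data = np.stack(bands)
        return cls(names, data, x0=xll, y0=yll + data.shape[1] * cs,
                   cell_size=cs, crs=crs)


def write_ascii_grid(path: str, band: np.ndarray, xll: float, yll: float,
                     cell_size: float, nodata: float = -9999.0) -> None:
    band = np.asarray(band, dtype=float)
    out = np.where(np.isfinite(band), band, nodata)
    header = (f"ncols {band.shape[1]}\nnrows {band.shape[0]}\n"
              f"xllcorner {xll}\nyllcorner {yll}\n"
              f"cellsize {cell_size}\nNODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str):
    """Read an ESRI ASCII grid; returns (band, (xll, yll, cellsize))."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        band = np.loadtxt(fh)
    band = np.atleast_2d(band)
    nodata = header.get("nodata_value")
    if nodata is not None:
        band = np.where(band == nodata, np.nan, band)
    meta = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0),
            header.get("cellsize", 1.0))
    return band, meta


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
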