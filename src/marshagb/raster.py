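"""Georeferenced raster containers and plain-text (ESRI ASCII grid) I/O.

Conventions
-----------
* Row 0 is the northernmost row; ``origin_x, origin_y`` is the *top-left*
  corner of the grid in projected metres.
* Pixel ``(r, c)`` covers the half-open square
  ``[x0 + c*s, x0 + (c+1)*s) × (y0 - (r+1)*s, y0 - r*s]``
  so every point belongs to exactly one pixel.
* Missing data is ``NaN`` in memory and the NODATA value on disk.
* Boolean masks are stored as 1.0 / 0.0 rasters (255 as the on-disk
  missing marker, NaN in memory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GridMismatchError, OutOfExtentError

#: metres per degree of latitude, used when a local metric grid must be
#: mapped to latitudes (e.g. the 47°N regional split)
METRES_PER_DEGREE = 111_320.0


@dataclass(frozen=True)
class RasterGrid:
    """Shape and georeferencing of a regular raster grid."""

    nrows: int
    ncols: int
    origin_x: float
    origin_y: float
    pixel_size: float
    crs_id: str = "local-metres"

    def __post_init__(self):
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid must be at least 1×1, got {self.nrows}×{self.ncols}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the full grid footprint."""
        s = self.pixel_size
        return (
            self.origin_x,
            self.origin_x + self.ncols * s,
            self.origin_y - self.nrows * s,
            self.origin_y,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.nrows) + 0.5) * self.pixel_size

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        s = self.pixel_size
        return (self.origin_x + (col + 0.5) * s, self.origin_y - (row + 0.5) * s)

    def contains(self, x: float, y: float) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return xmin <= x < xmax and ymin < y <= ymax

    def point_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Containing pixel under the half-open convention."""
        if not self.contains(x, y):
            raise OutOfExtentError(f"point ({x}, {y}) outside grid extent {self.extent}")
        s = self.pixel_size
        col = int(math.floor((x - self.origin_x) / s))
        row = int(math.floor((self.origin_y - y) / s))
        # top edge: y == origin_y gives row 0, not -1
        row = min(max(row, 0), self.nrows - 1)
        col = min(max(col, 0), self.ncols - 1)
        return row, col

    def nearest_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel whose *center* is nearest to the point.

        Ties on a pixel boundary break toward the smaller row, then the
        smaller column index.  Raises :class:`OutOfExtentError` for points
        outside the grid footprint.
        """
        if not self.contains(x, y):
            raise OutOfExtentError(f"point ({x}, {y}) outside grid extent {self.extent}")
        s = self.pixel_size
        # fractional index of the nearest center; exact .5 means the point
        # sits on a boundary between two centers -> take the smaller index
        fc = (x - self.origin_x) / s - 0.5
        fr = (self.origin_y - y) / s - 0.5
        col = int(math.ceil(fc - 0.5))
        row = int(math.ceil(fr - 0.5))
        return (min(max(row, 0), self.nrows - 1), min(max(col, 0), self.ncols - 1))

    def latitude_raster(self, lat_of_origin: float,
                        metres_per_degree: float = METRES_PER_DEGREE) -> "Raster":
        """Per-pixel latitude assuming a north-up local metric projection.

        ``lat_of_origin`` is the latitude of the grid's top edge; latitude
        decreases southward at ``metres_per_degree`` per degree.
        """
        lat_rows = lat_of_origin - (np.arange(self.nrows) + 0.5) * self.pixel_size / metres_per_degree
        values = np.broadcast_to(lat_rows[:, None], self.shape).copy()
        return Raster(self, values)


@dataclass
class Raster:
    """A single-band raster: grid plus a 2-D float array with NaN missing."""

    grid: RasterGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def full(cls, grid: RasterGrid, fill: float) -> "Raster":
        return cls(grid, np.full(grid.shape, float(fill)))

    @classmethod
    def from_bool(cls, grid: RasterGrid, mask: np.ndarray) -> "Raster":
        return cls(grid, np.asarray(mask, dtype=float))

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())

    def is_missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def as_bool(self) -> np.ndarray:
        """Interpret as a boolean mask; missing counts as False."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.values, nan=0.0) >= 0.5

    def same_grid(self, other: "Raster") -> bool:
        return self.grid == other.grid


def require_same_grid(*rasters: Raster) -> None:
    first = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != first:
            raise GridMismatchError(f"grids differ: {first} vs {r.grid}")


@dataclass
class AnnualStack:
    """One raster layer per year on a shared grid.

    ``values`` is ``(n_years, nrows, ncols)``; years are strictly increasing.
    """

    grid: RasterGrid
    years: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError(f"years must be strictly increasing, got {self.years}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years),) + self.grid.shape:
            raise ValueError(
                f"stack shape {self.values.shape} inconsistent with "
                f"{len(self.years)} years on grid {self.grid.shape}"
            )

    @classmethod
    def from_layers(cls, years: Sequence[int], layers: Iterable[Raster]) -> "AnnualStack":
        layers = list(layers)
        require_same_grid(*layers)
        return cls(layers[0].grid, tuple(years), np.stack([l.values for l in layers]))

    def layer(self, year: int) -> Raster:
        try:
            idx = self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in stack years {self.years}") from None
        return Raster(self.grid, self.values[idx])

    def __len__(self) -> int:
        return len(self.years)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain text; NODATA encodes missing)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0,
                     fmt: str = "%.6g") -> None:
    """Write a raster as an ESRI ASCII grid (.asc).

    The CRS label is recorded in a sidecar ``.prj`` text file.
    """
    path = Path(path)
    g = raster.grid
    xll = g.origin_x
    yll = g.origin_y - g.nrows * g.pixel_size
    vals = raster.values.copy()
    vals[np.isnan(vals)] = nodata
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.pixel_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    path.with_suffix(".prj").write_text(g.crs_id + "\n")


def read_ascii_grid(path: str | Path, crs_id: str | None = None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    if crs_id is None:
        prj = path.with_suffix(".prj")
        crs_id = prj.read_text().strip() if prj.exists() else "local-metres"
    size = header["cellsize"]
    grid = RasterGrid(
        nrows=nrows,
        ncols=ncols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * size,
        pixel_size=size,
        crs_id=crs_id,
    )
    return Raster(grid, vals)


def write_mask_ascii(mask: Raster, path: str | Path) -> None:
    """Write a boolean mask raster with 1/0 values and 255 as missing."""
    out = mask.copy()
    write_ascii_grid(out, path, nodata=255.0, fmt="%d")


def read_mask_ascii(path: str | Path) -> Raster:
    return read_ascii_grid(path)
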