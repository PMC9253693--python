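"""Stable-mask extraction, maximum-value compositing, and site pairing.

The stable marsh mask is the pixelwise intersection of two epoch extent
maps; analysing only pixels that are marsh in both epochs removes areas
converted to or from marsh between the epochs.  Within-year NDVI
composites are reduced to an annual maximum (maximum-value compositing,
MVC), which suppresses cloud and atmosphere artifacts and serves as the
peak-greenness proxy for standing biomass.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .errors import OutOfExtentError
from .raster import AnnualStack, Raster, RasterGrid, require_same_grid


def stable_marsh_mask(mask_t1: Raster, mask_t2: Raster) -> Raster:
    """Intersection of two epoch masks: true exactly where both are true.

    Missing cells count as "not marsh" in either epoch.
    """
    require_same_grid(mask_t1, mask_t2)
    both = mask_t1.as_bool() & mask_t2.as_bool()
    return Raster.from_bool(mask_t1.grid, both)


def resample_mask_majority(src: Raster, dst_grid: RasterGrid) -> Raster:
    """Aggregate a fine boolean mask onto a coarser grid by majority rule.

    Each destination pixel takes the majority vote of the source pixel
    centers it contains (>= half true -> true).  Destination pixels
    containing no valid source center are missing.
    """
    sg = src.grid
    xs = sg.x_centers()
    ys = sg.y_centers()
    s = dst_grid.pixel_size
    cols = np.floor((xs - dst_grid.origin_x) / s).astype(int)
    rows = np.floor((dst_grid.origin_y - ys) / s).astype(int)
    ok_c = (cols >= 0) & (cols < dst_grid.ncols)
    ok_r = (rows >= 0) & (rows < dst_grid.nrows)

    valid_src = ~src.is_missing()
    true_src = src.as_bool()
    n_valid = np.zeros(dst_grid.shape)
    n_true = np.zeros(dst_grid.shape)
    rr = np.broadcast_to(rows[:, None], src.values.shape)
    cc = np.broadcast_to(cols[None, :], src.values.shape)
    inside = np.broadcast_to(ok_r[:, None], src.values.shape) & np.broadcast_to(
        ok_c[None, :], src.values.shape
    )
    sel = inside & valid_src
    np.add.at(n_valid, (rr[sel], cc[sel]), 1.0)
    sel_t = sel & true_src
    np.add.at(n_true, (rr[sel_t], cc[sel_t]), 1.0)

    out = np.full(dst_grid.shape, np.nan)
    has = n_valid > 0
    out[has] = (n_true[has] >= 0.5 * n_valid[has]).astype(float)
    return Raster(dst_grid, out)


def annual_ndvi_max(composites: Sequence[Raster]) -> Raster:
    """Per-pixel maximum over within-year composites, ignoring missing.

    A pixel is missing in the output only if it is missing in *every*
    composite.
    """
    if len(composites) == 0:
        raise ValueError("at least one composite is required")
    require_same_grid(*composites)
    stack = np.stack([c.values for c in composites])
    with np.errstate(all="ignore"):
        out = np.full(stack.shape[1:], np.nan)
        any_valid = ~np.all(np.isnan(stack), axis=0)
        out[any_valid] = np.nanmax(stack[:, any_valid], axis=0)
    return Raster(composites[0].grid, out)


def annual_max_stack(composites_by_year: Mapping[int, Sequence[Raster]]) -> AnnualStack:
    """Build the NDVI_max annual stack from per-year composite lists."""
    years = sorted(composites_by_year)
    layers = [annual_ndvi_max(composites_by_year[y]) for y in years]
    return AnnualStack.from_layers(years, layers)


def site_ndvi_max(stack: AnnualStack, x: float, y: float, year: int) -> float:
    """NDVI_max of the pixel containing a field site in the site's year.

    Uses the nearest-pixel-center rule at boundaries (ties toward the
    smaller row, then smaller column).  Returns NaN — a missing-value
    signal, not an error — when the pixel has no NDVI that year.
    """
    layer = stack.layer(year)
    try:
        row, col = stack.grid.nearest_rowcol(x, y)
    except OutOfExtentError:
        raise
    return float(layer.values[row, col])
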