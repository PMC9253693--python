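"""Per-pixel and regional trend and correlation statistics.

The per-pixel trend is the least-squares linear slope of an annual series
against the year index i = 1..n, computed in normal-equation form:

    slope = (n·Σ i·y_i − Σ i · Σ y_i) / (n·Σ i² − (Σ i)²)

Correlation is the Pearson coefficient.  Significance of both uses the
classical t statistic with n − 2 degrees of freedom; no multiple-testing
correction is applied across the 13×4 month/variable table or across
pixels — a deliberate caveat documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, EmptyRegionError
from .raster import AnnualStack, Raster, require_same_grid

logger = logging.getLogger(__name__)

MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)
PERIOD_ROWS = ("Annual",) + MONTH_NAMES
TABLE_COLUMNS = ("precip", "tmean", "tmax", "tmin")


def theta_slope(series: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Least-squares linear slope per year of an annual series.

    Vectorised over leading axes; requires n ≥ 3 finite values along
    ``axis`` (series with any missing value yield NaN).
    """
    y = np.asarray(series, dtype=float)
    y = np.moveaxis(y, axis, -1)
    n = y.shape[-1]
    if n < 3:
        raise ValueError(f"series length must be at least 3, got {n}")
    i = np.arange(1, n + 1, dtype=float)
    sum_i = i.sum()
    sum_i2 = (i**2).sum()
    num = n * (y * i).sum(axis=-1) - sum_i * y.sum(axis=-1)
    den = n * sum_i2 - sum_i**2
    out = num / den
    bad = ~np.isfinite(y).all(axis=-1)
    if np.ndim(out) == 0:
        return float("nan") if bad else float(out)
    out[bad] = np.nan
    return out


def slope_significance(series: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Two-sided p-value of the trend's t statistic (n − 2 df).

    Zero residual variance gives p = 0 by convention (an exact line is an
    unambiguous trend); this is logged once per call.
    """
    y = np.asarray(series, dtype=float)
    y = np.moveaxis(y, axis, -1)
    n = y.shape[-1]
    if n < 3:
        raise ValueError(f"series length must be at least 3, got {n}")
    i = np.arange(1, n + 1, dtype=float)
    slope = theta_slope(y, axis=-1)
    intercept = y.mean(axis=-1) - np.asarray(slope) * i.mean()
    resid = y - (np.expand_dims(np.asarray(slope), -1) * i
                 + np.expand_dims(np.asarray(intercept), -1))
    sse = (resid**2).sum(axis=-1)
    sxx = ((i - i.mean()) ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = np.asarray(slope) / se
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    zero_var = (sse <= 0) & np.isfinite(np.asarray(slope))
    if np.any(zero_var):
        logger.warning("zero residual variance in %d series; p set to 0", int(np.sum(zero_var)))
        p = np.where(zero_var, 0.0, p)
    p = np.where(np.isfinite(np.asarray(slope)), p, np.nan)
    return float(p) if np.ndim(p) == 0 or p.shape == () else p


def pearson_r(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Pearson correlation; NaN where either series has zero variance."""
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    y = np.moveaxis(np.asarray(y, dtype=float), axis, -1)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(f"series lengths differ: {x.shape[-1]} vs {y.shape[-1]}")
    if x.shape[-1] < 3:
        raise ValueError("series length must be at least 3")
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=-1) / np.sqrt(
            (xc**2).sum(axis=-1) * (yc**2).sum(axis=-1)
        )
    r = np.clip(r, -1.0, 1.0)
    return float(r) if np.ndim(r) == 0 else r


def pearson_p(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p-value of Pearson r via the t transform (n − 2 df)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    return float(p) if np.ndim(p) == 0 or p.shape == () else p


@dataclass
class StatMap:
    """A per-pixel statistic raster with its significance raster."""

    kind: str  # "trend" | "correlation"
    variable: str
    values: Raster
    p_values: Raster


def _require_aligned(a: AnnualStack, b: AnnualStack) -> None:
    if a.grid != b.grid:
        raise AlignmentError("stacks are on different grids")
    if a.years != b.years:
        extra_a = sorted(set(a.years) - set(b.years))
        extra_b = sorted(set(b.years) - set(a.years))
        raise AlignmentError(
            f"year mismatch: only-first={extra_a}, only-second={extra_b}"
        )


def pixelwise_map(agb_stack: AnnualStack, covariate_stack: AnnualStack | None,
                  mask: Raster, kind: str, variable: str = "AGB") -> StatMap:
    """Per-pixel trend or correlation over the masked region.

    A pixel enters the map only if it is masked and has all years present
    (missing pixels are skipped, not imputed).
    """
    if kind not in ("trend", "correlation"):
        raise ValueError(f"kind must be 'trend' or 'correlation', got {kind!r}")
    require_same_grid(agb_stack.layer(agb_stack.years[0]), mask)
    y = np.moveaxis(agb_stack.values, 0, -1)  # (nrows, ncols, nyears)
    ok = mask.as_bool() & np.isfinite(y).all(axis=-1)
    n = len(agb_stack.years)
    vals = np.full(mask.grid.shape, np.nan)
    pvals = np.full(mask.grid.shape, np.nan)
    if kind == "trend":
        if covariate_stack is not None:
            raise ValueError("trend maps take no covariate stack")
        vals[ok] = theta_slope(y[ok], axis=-1)
        pvals[ok] = slope_significance(y[ok], axis=-1)
    else:
        if covariate_stack is None:
            raise ValueError("correlation maps require a covariate stack")
        _require_aligned(agb_stack, covariate_stack)
        x = np.moveaxis(covariate_stack.values, 0, -1)
        ok &= np.isfinite(x).all(axis=-1)
        r = pearson_r(x[ok], y[ok], axis=-1)
        vals[ok] = r
        pvals[ok] = pearson_p(r, n)
    return StatMap(kind=kind, variable=variable,
                   values=Raster(mask.grid, vals), p_values=Raster(mask.grid, pvals))


def regional_series(stack: AnnualStack, mask: Raster) -> pd.Series:
    """Per-year mean over masked, non-missing pixels.

    A year with no valid masked pixel yields NaN and a logged warning.
    """
    require_same_grid(stack.layer(stack.years[0]), mask)
    m = mask.as_bool()
    if not m.any():
        raise EmptyRegionError("mask")
    out = []
    for k, year in enumerate(stack.years):
        vals = stack.values[k][m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("year %d has no valid masked pixels; regional mean is NaN", year)
            out.append(np.nan)
        else:
            out.append(float(vals.mean()))
    return pd.Series(out, index=list(stack.years), name="regional_mean")


@dataclass
class CorrelationTable:
    """13 × 4 table of Pearson r (Annual + 12 months × 4 climate variables).

    ``r`` and ``p`` are DataFrames with rows Annual, January..December and
    columns precip, tmean, tmax, tmin; stars flag p<0.05 (*) / p<0.01 (**).
    """

    r: pd.DataFrame
    p: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        def mark(p):
            if np.isnan(p):
                return ""
            return "**" if p < 0.01 else "*" if p < 0.05 else ""

        return self.p.map(mark)

    def to_csv(self, path: str | Path) -> None:
        out = self.r.round(4).astype(object).copy()
        stars = self.stars()
        for c in out.columns:
            out[c + "_sig"] = stars[c]
        out.to_csv(path, index_label="period")


def correlation_table(agb_series: pd.Series,
                      climate_series: Mapping[tuple[str, int | str], pd.Series]
                      ) -> CorrelationTable:
    """Regional AGB vs regional climate correlations, by period and variable.

    ``climate_series`` maps (variable, period) — period "annual" or 1..12 —
    to a per-year regional series aligned with ``agb_series``.
    """
    n = len(agb_series)
    r = pd.DataFrame(np.nan, index=list(PERIOD_ROWS), columns=list(TABLE_COLUMNS))
    p = r.copy()
    y = agb_series.to_numpy(dtype=float)
    for var in TABLE_COLUMNS:
        for row, period in zip(PERIOD_ROWS, ["annual"] + list(range(1, 13))):
            key = (var, period)
            if key not in climate_series:
                continue
            x = climate_series[key]
            if len(x) != n or list(x.index) != list(agb_series.index):
                raise AlignmentError(
                    f"climate series {key} years do not match AGB years"
                )
            rv = pearson_r(x.to_numpy(dtype=float), y)
            r.loc[row, var] = rv
            p.loc[row, var] = pearson_p(rv, n)
    return CorrelationTable(r=r, p=p)


def latitude_split(agb_stack: AnnualStack,
                   climate_stacks: Mapping[tuple[str, int | str], AnnualStack],
                   mask: Raster, latitudes: Raster,
                   threshold_deg: float = 47.0) -> dict[str, CorrelationTable]:
    """Correlation tables for pixels south (≤ threshold) and north (>) of a parallel.

    Regional AGB and climate series are recomputed within each sub-region
    before correlating.  An empty sub-region raises
    :class:`EmptyRegionError` naming the region.
    """
    require_same_grid(mask, latitudes)
    out: dict[str, CorrelationTable] = {}
    south = mask.as_bool() & (latitudes.values <= threshold_deg)
    north = mask.as_bool() & (latitudes.values > threshold_deg)
    for name, sub in (("south", south), ("north", north)):
        if not sub.any():
            raise EmptyRegionError(name)
        submask = Raster.from_bool(mask.grid, sub)
        agb_series = regional_series(agb_stack, submask)
        clim = {k: regional_series(st, submask) for k, st in climate_stacks.items()}
        out[name] = correlation_table(agb_series, clim)
    return out


def write_statmap_ascii(sm: StatMap, value_path: str | Path, p_path: str | Path) -> None:
    from .raster import write_ascii_grid

    write_ascii_grid(sm.values, value_path)
    write_ascii_grid(sm.p_values, p_path)
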