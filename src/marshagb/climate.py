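"""Station climate aggregation and ordinary kriging onto the analysis grid.

Monthly station records (precipitation, Tmin, Tmax, Tmean) are aggregated
to the requested period — monthly values pass through, annual precipitation
is the 12-month sum, annual temperature the 12-month mean — and then
interpolated to the raster grid by ordinary kriging with a spherical
semivariogram fitted to the empirical variogram by weighted least squares.
Kriging operates in projected metres on the grid's CRS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist, squareform

from .raster import Raster, RasterGrid

logger = logging.getLogger(__name__)

VARIABLES = ("precip", "tmin", "tmax", "tmean")
_COLUMNS = {"precip": "precip_mm", "tmin": "tmin_c", "tmax": "tmax_c", "tmean": "tmean_c"}


@dataclass
class StationRecord:
    """One meteorological station's monthly series.

    ``series`` is indexed by (year, month) with columns
    precip_mm, tmin_c, tmax_c, tmean_c.
    """

    station_id: str
    x: float
    y: float
    series: pd.DataFrame

    def __post_init__(self):
        months = self.series.index.get_level_values("month")
        if len(months) and (months.min() < 1 or months.max() > 12):
            raise ValueError("months must lie in 1–12")


@dataclass
class ClimateField:
    variable: str
    year: int
    period: int | str  # 1..12 or "annual"
    surface: Raster


def station_period_value(record: StationRecord, year: int,
                         period: int | str, variable: str) -> float:
    """Aggregate one station to a (year, period) value.

    Monthly periods return the stored value; "annual" sums precipitation
    and averages temperatures over the 12 months.  A missing month inside
    an annual request yields NaN (a missing-value signal, not an error).
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    col = _COLUMNS[variable]
    if period == "annual":
        try:
            months = record.series.loc[year, col]
        except KeyError:
            return float("nan")
        if len(months) < 12 or months.isna().any():
            return float("nan")
        return float(months.sum()) if variable == "precip" else float(months.mean())
    month = int(period)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1–12 or 'annual', got {period!r}")
    try:
        return float(record.series.loc[(year, month), col])
    except KeyError:
        return float("nan")


# ---------------------------------------------------------------------------
# ordinary kriging with a spherical semivariogram
# ---------------------------------------------------------------------------

def spherical_semivariance(h, nugget: float, psill: float, rng: float):
    """Spherical model; gamma(0)=0 so kriging is exact at data points."""
    h = np.asarray(h, dtype=float)
    hr = np.minimum(h / max(rng, 1e-300), 1.0)
    gamma = nugget + psill * (1.5 * hr - 0.5 * hr**3)
    return np.where(h == 0.0, 0.0, gamma)


def empirical_variogram(points: np.ndarray, values: np.ndarray,
                        n_bins: int = 12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram: (bin centers, semivariances, counts)."""
    d = pdist(points)
    gamma = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, d.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sv = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins)
    for k in range(n_bins):
        sel = idx == k
        counts[k] = sel.sum()
        if counts[k]:
            sv[k] = gamma[sel].mean()
    ok = counts > 0
    return centers[ok], sv[ok], counts[ok]


def fit_spherical_variogram(points: np.ndarray, values: np.ndarray,
                            n_bins: int = 12) -> tuple[float, float, float]:
    """Fit (nugget, partial sill, range) by count-weighted least squares."""
    centers, sv, counts = empirical_variogram(points, values, n_bins)
    var = float(np.var(values))
    dmax = float(pdist(points).max())
    if var == 0.0 or len(centers) < 3:
        return 0.0, max(var, 1e-12), max(dmax / 2, 1e-9)
    p0 = (0.0, var, dmax / 2)
    try:
        popt, _ = curve_fit(
            spherical_semivariance, centers, sv, p0=p0,
            sigma=1.0 / np.sqrt(counts), absolute_sigma=False,
            bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, 10 * dmax]),
            maxfev=10000,
        )
        nugget, psill, rng = (float(v) for v in popt)
    except Exception as exc:
        logger.warning("variogram fit failed (%s); using moment defaults", exc)
        nugget, psill, rng = 0.0, var, dmax / 2
    return nugget, psill, rng


def inverse_distance(points: np.ndarray, values: np.ndarray,
                     grid: RasterGrid, power: float = 2.0) -> Raster:
    """Inverse-distance-weighted fallback interpolator."""
    gx, gy = np.meshgrid(grid.x_centers(), grid.y_centers())
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    d = cdist(targets, points)
    out = np.empty(len(targets))
    exact = d < 1e-9
    hits = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[hits] = 0.0
    out[~hits] = (w[~hits] @ values) / w[~hits].sum(axis=1)
    if hits.any():
        out[hits] = values[np.argmax(exact[hits], axis=1)]
    return Raster(grid, out.reshape(grid.shape))


def krige_field(stations: Sequence[tuple[float, float, float]],
                grid: RasterGrid, n_bins: int = 12) -> Raster:
    """Ordinary kriging of station (x, y, value) triples onto a grid.

    Fewer than 3 usable stations falls back to inverse-distance weighting
    with a logged warning; a singular kriging system is jittered and
    retried once before falling back.
    """
    arr = np.asarray(stations, dtype=float)
    arr = arr[np.isfinite(arr).all(axis=1)]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("stations must be (x, y, value) triples")
    points, values = arr[:, :2], arr[:, 2]
    if len(points) < 3:
        logger.warning("only %d station(s); falling back to inverse-distance weighting",
                       len(points))
        return inverse_distance(points, values, grid)
    if np.ptp(values) < 1e-12:
        # constant field: kriging is exactly the constant
        return Raster.full(grid, float(values[0]))

    nugget, psill, rng = fit_spherical_variogram(points, values, n_bins)

    n = len(points)
    gamma_ij = spherical_semivariance(squareform(pdist(points)), nugget, psill, rng)
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = gamma_ij
    lhs[n, :n] = 1.0
    lhs[:n, n] = 1.0
    lhs[n, n] = 0.0

    gx, gy = np.meshgrid(grid.x_centers(), grid.y_centers())
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    gamma_0 = spherical_semivariance(cdist(points, targets), nugget, psill, rng)
    rhs = np.vstack([gamma_0, np.ones(len(targets))])

    for attempt in range(2):
        try:
            weights = np.linalg.solve(lhs, rhs)
            break
        except np.linalg.LinAlgError:
            if attempt == 0:
                logger.warning("singular kriging system; jittering diagonal and retrying")
                lhs[:n, :n] += np.eye(n) * max(psill, 1.0) * 1e-10
            else:
                logger.warning("kriging system still singular; inverse-distance fallback")
                return inverse_distance(points, values, grid)
    est = weights[:n].T @ values
    return Raster(grid, est.reshape(grid.shape))


def krige_station_period(records: Sequence[StationRecord], grid: RasterGrid,
                         year: int, period: int | str, variable: str) -> ClimateField:
    """Aggregate every station to (year, period) and krige the result."""
    triples = [
        (r.x, r.y, station_period_value(r, year, period, variable)) for r in records
    ]
    triples = [t for t in triples if np.isfinite(t[2])]
    surface = krige_field(triples, grid)
    return ClimateField(variable=variable, year=year, period=period, surface=surface)


# ---------------------------------------------------------------------------
# stations CSV I/O
# schema: station_id, lon, lat, year, month, precip_mm, tmin_c, tmax_c, tmean_c
# ---------------------------------------------------------------------------

def write_stations_csv(records: Sequence[StationRecord], path: str | Path) -> None:
    frames = []
    for r in records:
        df = r.series.reset_index()
        df.insert(0, "station_id", r.station_id)
        df.insert(1, "lon", r.x)
        df.insert(2, "lat", r.y)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stations_csv(path: str | Path) -> list[StationRecord]:
    df = pd.read_csv(path)
    records = []
    for sid, g in df.groupby("station_id", sort=True):
        series = g.set_index(["year", "month"])[
            ["precip_mm", "tmin_c", "tmax_c", "tmean_c"]
        ].sort_index()
        records.append(
            StationRecord(station_id=str(sid), x=float(g.lon.iloc[0]),
                          y=float(g.lat.iloc[0]), series=series)
        )
    return records
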