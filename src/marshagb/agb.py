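"""Biomass calibration: quadrats → carbon density, NDVI_max → AGB model.

Field sites contribute the mean dry biomass of three 1 m² quadrats,
converted to carbon with the standard 0.45 carbon fraction.  Candidate
regression forms relate a site's annual NDVI maximum to its AGB carbon
density; the form with the highest coefficient of determination on the
original (untransformed) AGB scale is selected.  The fitted model is then
applied per pixel over the stable marsh mask and aggregated to a regional
mean density and total carbon stock.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyRegionError, ModelSelectionError
from .raster import Raster, require_same_grid

logger = logging.getLogger(__name__)

#: dry biomass → carbon conversion coefficient
CARBON_FRACTION = 0.45

#: candidate forms in selection-preference order (ties break earlier-first)
FORM_ORDER = ("power", "linear", "exponential", "logarithmic")


def site_carbon_density(quadrats: Sequence[float]) -> float:
    """AGB carbon density (g·C/m²) from three quadrat dry masses (g/m²).

    The site value is the arithmetic mean of the three quadrats times the
    0.45 carbon fraction.
    """
    q = np.asarray(quadrats, dtype=float)
    if q.shape != (3,):
        raise ValueError(f"exactly three quadrat values required, got shape {q.shape}")
    if np.any(q < 0):
        raise ValueError(f"quadrat biomass must be non-negative, got {q.tolist()}")
    return float(CARBON_FRACTION * q.mean())


@dataclass
class SampleSite:
    """One field site: location, sampling year, quadrats, derived values."""

    site_id: str
    x: float
    y: float
    year: int
    quadrat_biomass: tuple[float, float, float]
    agb_density: float = field(default=float("nan"))
    ndvi_max: float = field(default=float("nan"))

    def __post_init__(self):
        self.quadrat_biomass = tuple(float(q) for q in self.quadrat_biomass)
        if np.isnan(self.agb_density):
            self.agb_density = site_carbon_density(self.quadrat_biomass)


@dataclass
class CalibratedModel:
    """A fitted NDVI_max → AGB carbon density model.

    Functional forms (x = NDVI_max, y = AGB density in g·C/m²)::

        power        y = a * x**b
        linear       y = a * x + b
        exponential  y = a * exp(b * x)
        logarithmic  y = a + b * ln(x)
    """

    form: str
    a: float
    b: float
    r_squared: float = float("nan")
    rmse: float = float("nan")
    relative_error_pct: float = float("nan")
    n: int = 0
    fit_ok: bool = True
    message: str = ""

    def __post_init__(self):
        if self.form not in FORM_ORDER:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.form == "power" and self.fit_ok and not self.a > 0:
            raise ValueError(f"power-form coefficient must be positive, got {self.a}")

    @property
    def n_params(self) -> int:
        return 2

    def predict(self, x):
        """Evaluate the model; array-safe, NaN-propagating."""
        if not self.fit_ok:
            raise RuntimeError(f"model ({self.form}) was not successfully fitted: {self.message}")
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.form == "power":
                y = self.a * np.power(x, self.b)
            elif self.form == "linear":
                y = self.a * x + self.b
            elif self.form == "exponential":
                y = self.a * np.exp(self.b * x)
            else:  # logarithmic
                y = self.a + self.b * np.log(x)
        return y if y.shape else float(y)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibratedModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _fit_one(form: str, x: np.ndarray, y: np.ndarray) -> CalibratedModel:
    try:
        if form == "power":
            # init from log–log OLS, refine by NLS on the original scale
            # (log–log-only fitting biases the coefficient a)
            ok = (x > 0) & (y > 0)
            if ok.sum() >= 2:
                b0, loga0 = np.polyfit(np.log(x[ok]), np.log(y[ok]), 1)
                p0 = (float(np.exp(loga0)), float(b0))
            else:
                p0 = (1.0, 1.0)
            popt, _ = curve_fit(
                lambda t, a, b: a * np.power(t, b), x, y, p0=p0, maxfev=20000
            )
            a, b = float(popt[0]), float(popt[1])
            yhat = a * np.power(x, b)
        elif form == "linear":
            a, b = (float(v) for v in np.polyfit(x, y, 1))
            yhat = a * x + b
        elif form == "exponential":
            ok = y > 0
            if ok.sum() >= 2:
                b0, loga0 = np.polyfit(x[ok], np.log(y[ok]), 1)
                p0 = (float(np.exp(loga0)), float(b0))
            else:
                p0 = (1.0, 1.0)
            popt, _ = curve_fit(
                lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=20000
            )
            a, b = float(popt[0]), float(popt[1])
            yhat = a * np.exp(b * x)
        else:  # logarithmic
            if np.any(x <= 0):
                raise ValueError("logarithmic form requires positive x")
            b, a = (float(v) for v in np.polyfit(np.log(x), y, 1))
            yhat = a + b * np.log(x)
        if not (np.all(np.isfinite([a, b])) and np.all(np.isfinite(yhat))):
            raise ValueError("non-finite fit result")
    except Exception as exc:  # degenerate input → flagged, not raised
        return CalibratedModel(
            form=form, a=float("nan"), b=float("nan"), r_squared=-np.inf,
            n=len(x), fit_ok=False, message=str(exc),
        )
    model = CalibratedModel(form=form, a=a, b=b, r_squared=_r_squared(y, yhat), n=len(x))
    model.rmse, model.relative_error_pct = validate(model, list(zip(x, y)))
    return model


def fit_candidates(pairs: Sequence[tuple[float, float]]) -> list[CalibratedModel]:
    """Fit every candidate form to (NDVI_max, AGB density) pairs.

    R² is always computed on the original AGB scale so forms fitted in a
    transformed space compete fairly.  Degenerate inputs (e.g. all NDVI
    identical) yield models flagged ``fit_ok=False`` rather than raising.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("at least three (ndvi_max, agb) pairs are required")
    x, y = arr[:, 0], arr[:, 1]
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("pairs contain non-finite values")
    if np.any(x <= 0):
        raise ValueError("ndvi_max values must be positive for calibration")
    if np.allclose(x, x[0]):
        return [
            CalibratedModel(form=f, a=float("nan"), b=float("nan"), r_squared=-np.inf,
                            n=len(x), fit_ok=False, message="degenerate input: all x identical")
            for f in FORM_ORDER
        ]
    return [_fit_one(f, x, y) for f in FORM_ORDER]


def select_best(models: Sequence[CalibratedModel]) -> CalibratedModel:
    """Highest-R² model; ties break by fewer parameters, then form order."""
    usable = [m for m in models if m.fit_ok]
    if not usable:
        raise ModelSelectionError("all candidate fits failed")
    return min(
        usable,
        key=lambda m: (-m.r_squared, m.n_params, FORM_ORDER.index(m.form)),
    )


def validate(model: CalibratedModel, pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """RMSE (g·C/m²) and mean per-sample relative error (%) of predictions.

    RMSE = sqrt(mean of squared residuals); relative error is the mean of
    100·|obs − est|/obs over samples.  Samples with zero observed AGB are
    excluded from the relative error with a logged warning.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("at least one (ndvi_max, agb) pair is required")
    x, y = arr[:, 0], arr[:, 1]
    est = np.asarray(model.predict(x), dtype=float)
    rmse = float(np.sqrt(np.mean((est - y) ** 2)))
    nonzero = y != 0
    if not np.all(nonzero):
        logger.warning(
            "relative error undefined for %d sample(s) with zero observed AGB; excluded",
            int((~nonzero).sum()),
        )
    if nonzero.any():
        rel = float(100.0 * np.mean(np.abs(y[nonzero] - est[nonzero]) / y[nonzero]))
    else:
        rel = float("nan")
    return rmse, rel


def predict_raster(model: CalibratedModel, ndvi_max: Raster, mask: Raster) -> Raster:
    """Apply the model per pixel inside the mask.

    NDVI is clipped to [0, 1] before evaluation; pixels outside the mask or
    with missing NDVI are missing in the output.
    """
    require_same_grid(ndvi_max, mask)
    if not model.fit_ok:
        raise RuntimeError("cannot predict from a model whose fit failed")
    inside = mask.as_bool() & ~ndvi_max.is_missing()
    out = np.full(ndvi_max.grid.shape, np.nan)
    x = np.clip(ndvi_max.values[inside], 0.0, 1.0)
    with np.errstate(divide="ignore"):
        out[inside] = model.predict(x)
    return Raster(ndvi_max.grid, out)


@dataclass(frozen=True)
class RegionalSummary:
    mean_density: float   # g·C/m²
    area_m2: float
    total_TgC: float


def regional_summary(agb: Raster, mask: Raster) -> RegionalSummary:
    """Regional mean density, masked area, and total carbon stock.

    total (Tg·C) = mean density (g·C/m²) × area (m²) × 1e-12.
    """
    require_same_grid(agb, mask)
    m = mask.as_bool()
    if not m.any():
        raise EmptyRegionError("mask")
    vals = agb.values[m]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise EmptyRegionError("mask (all masked pixels missing)")
    mean_density = float(vals.mean())
    area = float(m.sum()) * agb.grid.pixel_size ** 2
    return RegionalSummary(mean_density, area, mean_density * area * 1e-12)


# ---------------------------------------------------------------------------
# sites CSV I/O (schema: site_id, lon, lat, year, quadrat1_g .. quadrat3_g)
# ---------------------------------------------------------------------------

def write_sites_csv(sites: Sequence[SampleSite], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "lon": [s.x for s in sites],
            "lat": [s.y for s in sites],
            "year": [s.year for s in sites],
            "quadrat1_g": [s.quadrat_biomass[0] for s in sites],
            "quadrat2_g": [s.quadrat_biomass[1] for s in sites],
            "quadrat3_g": [s.quadrat_biomass[2] for s in sites],
        }
    )
    df.to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[SampleSite]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        SampleSite(
            site_id=str(r.site_id),
            x=float(r.lon),
            y=float(r.lat),
            year=int(r.year),
            quadrat_biomass=(float(r.quadrat1_g), float(r.quadrat2_g), float(r.quadrat3_g)),
        )
        for r in df.itertuples(index=False)
    ]
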