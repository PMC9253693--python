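"""Synthetic marsh scenes with known ground truth.

Generates everything the pipeline consumes — two epoch marsh-extent masks,
a 16-day NDVI raster series, monthly station climate, and quadrat-level
field biomass samples — from a single seeded random stream, with the
generating parameters retained so every downstream stage has an exact
oracle.

Generating model
----------------
* Latent AGB carbon density at pixel p in year t:

      AGB(p, t) = clip(base(p) + trend(p)·(t − t_mid) + k_July·ΔT_July(t),
                       agb_min, agb_max)

  where base(p) is a smooth spatial field, trend(p) the injected linear
  trend (g·C/m²/a), and ΔT_July(t) the July mean-temperature anomaly of
  year t (spatially uniform), coupling vegetation to summer warmth.
* The clean annual NDVI peak is the inverse power law
  (AGB/a)^(1/b); the 16-day series is a squared-sine seasonal curve whose
  maximum equals that peak exactly, plus additive N(0, ndvi_noise_sd)
  observation noise, clipped to [−0.2, 1].
* Site quadrat biomass is latent AGB / 0.45 times a median-one lognormal
  multiplier with coefficient of variation ``agb_noise_cv``, so the power
  law stays exact in the median.
* Climate fields are deterministic seasonal + linear-trend + smooth
  spatial (plane + Gaussian bumps) terms plus spatially uniform
  year–month anomalies; stations sample the field exactly, so the truth
  at any station is closed-form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agb import CARBON_FRACTION, SampleSite, write_sites_csv
from .climate import StationRecord, write_stations_csv
from .errors import ConfigurationError
from .raster import AnnualStack, Raster, RasterGrid, write_ascii_grid, write_mask_ascii

DEFAULT_CLIMATE = {
    # per-variable deterministic structure; temperatures in °C, precip in mm/month
    "tmean": {"mean": 3.2, "seasonal_amplitude": 21.0, "trend_per_year": 0.04,
              "anomaly_sd": 1.2, "spatial_range": 3.0},
    "tmax": {"offset": 6.0, "trend_per_year": 0.04, "anomaly_sd": 0.3},
    "tmin": {"offset": -6.0, "trend_per_year": 0.05, "anomaly_sd": 0.3},
    "precip": {"annual_mean_mm": 550.0, "concentration": 1.8, "trend_per_year": 0.08,
               "lognorm_sigma": 0.30, "spatial_frac": 0.15},
}


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    Defaults mirror the observed-data layout: a 250 m grid, 21 years of
    23 sixteen-day composites, 21 stations, and 16 field sites sampled in
    2013–2017, with the published power law (a=643.57, b=4.2474) as the
    generating truth and its reported regional trend (2.47 g·C/m²/a) as
    the default injected AGB trend.
    """

    nrows: int = 100
    ncols: int = 100
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 250.0
    crs_id: str = "local-metres"
    years: tuple[int, ...] = tuple(range(2000, 2021))
    composites_per_year: int = 23
    n_stations: int = 21
    n_sites: int = 16
    site_years: tuple[int, ...] = tuple(range(2013, 2018))
    true_a: float = 643.57
    true_b: float = 4.2474
    ndvi_noise_sd: float = 0.02
    agb_noise_cv: float = 0.15
    agb_trend: float | np.ndarray = 2.47        # g·C/m²/a, scalar or (nrows, ncols)
    agb_base_range: tuple[float, float] = (90.0, 520.0)
    agb_clip: tuple[float, float] = (10.0, 585.0)
    july_coupling: float = 15.0                 # g·C/m² per °C of July anomaly
    climate_trend_params: dict = field(default_factory=lambda: DEFAULT_CLIMATE)
    #: latitude of the grid's north edge; None places the 47°N parallel at
    #: the middle of the grid so both sub-regions of the split are populated
    lat_of_origin: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ConfigurationError("nrows/ncols", "grid must be at least 2×2")
        if self.composites_per_year < 1:
            raise ConfigurationError("composites_per_year", "must be ≥ 1")
        if not self.true_a > 0:
            raise ConfigurationError("true_a", "must be > 0")
        if not self.true_b > 0:
            raise ConfigurationError("true_b", "must be > 0")
        if self.ndvi_noise_sd < 0:
            raise ConfigurationError("ndvi_noise_sd", "must be ≥ 0")
        if self.agb_noise_cv < 0:
            raise ConfigurationError("agb_noise_cv", "must be ≥ 0")
        if len(self.years) < 1:
            raise ConfigurationError("years", "at least one year required")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites", "must be ≥ 1")
        if self.n_stations < 1:
            raise ConfigurationError("n_stations", "must be ≥ 1")
        if not set(self.site_years) & set(self.years):
            raise ConfigurationError("site_years", "no overlap with scene years")

    @property
    def grid(self) -> RasterGrid:
        return RasterGrid(self.nrows, self.ncols, self.origin_x, self.origin_y,
                          self.pixel_size, self.crs_id)

    @property
    def effective_lat_of_origin(self) -> float:
        from .raster import METRES_PER_DEGREE

        if self.lat_of_origin is not None:
            return self.lat_of_origin
        return 47.0 + self.nrows * self.pixel_size / (2 * METRES_PER_DEGREE)

    @classmethod
    def from_file(cls, path: str | Path) -> "SceneConfig":
        """Load a config from YAML or JSON."""
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "years" in data:
            data["years"] = tuple(data["years"])
        if "site_years" in data:
            data["site_years"] = tuple(data["site_years"])
        return cls(**data)


@dataclass
class SceneTruth:
    """Generating parameters sufficient to predict every downstream output."""

    true_a: float
    true_b: float
    trend_field: np.ndarray                  # (nrows, ncols), g·C/m²/a
    base_field: np.ndarray                   # (nrows, ncols), g·C/m²
    latent_agb: np.ndarray                   # (nyears, nrows, ncols)
    ndvi_peak: np.ndarray                    # (nyears, nrows, ncols), noise-free
    july_anomaly: np.ndarray                 # (nyears,), °C
    july_coupling: float
    climate_spatial: dict[str, np.ndarray]   # per-variable spatial term
    climate_anomaly: dict[str, np.ndarray]   # per-variable (nyears, 12)
    climate_params: dict

    def climate_field(self, config: "SceneConfig", variable: str,
                      year: int, month: int) -> np.ndarray:
        """Closed-form true monthly climate field on the grid."""
        yi = list(config.years).index(year)
        det = _climate_deterministic(config, variable, year, month)
        if variable == "precip":
            # spatial term is fractional, anomaly is a multiplicative
            # lognormal factor, so precipitation stays positive exactly
            return (det * (1.0 + self.climate_spatial["precip"])
                    * self.climate_anomaly["precip"][yi, month - 1])
        return (det + self.climate_spatial[variable]
                + self.climate_anomaly[variable][yi, month - 1])


@dataclass
class SyntheticScene:
    config: SceneConfig
    mask_epoch1: Raster
    mask_epoch2: Raster
    ndvi_composites: np.ndarray     # (nyears, composites, nrows, ncols)
    stations: list[StationRecord]
    sites: list[SampleSite]
    truth: SceneTruth

    @property
    def grid(self) -> RasterGrid:
        return self.config.grid

    def composites_for_year(self, year: int) -> list[Raster]:
        yi = list(self.config.years).index(year)
        return [Raster(self.grid, self.ndvi_composites[yi, c])
                for c in range(self.ndvi_composites.shape[1])]

    def true_agb_stack(self) -> AnnualStack:
        return AnnualStack(self.grid, self.config.years, self.truth.latent_agb.copy())


# ---------------------------------------------------------------------------
# smooth random fields
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, nrows: int, ncols: int,
                  n_bumps: int = 6) -> np.ndarray:
    """Plane + Gaussian bumps, normalised to [0, 1]."""
    r = (np.arange(nrows) + 0.5) / nrows
    c = (np.arange(ncols) + 0.5) / ncols
    rr, cc = np.meshgrid(r, c, indexing="ij")
    f = rng.uniform(-0.5, 0.5) * rr + rng.uniform(-0.5, 0.5) * cc
    for _ in range(n_bumps):
        cy, cx = rng.uniform(0, 1, 2)
        width = rng.uniform(0.12, 0.35)
        amp = rng.uniform(-1.0, 1.0)
        f += amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * width**2))
    f -= f.min()
    span = f.max()
    return f / span if span > 0 else np.zeros_like(f)


def _climate_deterministic(config: SceneConfig, variable: str,
                           year: int, month: int) -> float:
    """Seasonal + trend part of a climate variable (no spatial/anomaly term)."""
    p = config.climate_trend_params
    y_mid = float(np.mean(config.years))
    seas = np.cos(2 * np.pi * (month - 7) / 12.0)  # peaks in July
    if variable in ("tmean", "tmax", "tmin"):
        t = p["tmean"]["mean"] + p["tmean"]["seasonal_amplitude"] * seas
        t += p["tmean"]["trend_per_year"] * (year - y_mid)
        if variable != "tmean":
            t += p[variable]["offset"]
            extra = p[variable]["trend_per_year"] - p["tmean"]["trend_per_year"]
            t += extra * (year - y_mid)
        return float(t)
    # precip: monthly means concentrated on summer via a von-Mises-like weight
    kappa = p["precip"]["concentration"]
    w = np.exp(kappa * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12.0))
    w /= w.sum()
    base = p["precip"]["annual_mean_mm"] * w[month - 1]
    base += p["precip"]["trend_per_year"] * (year - y_mid) * 12 * w[month - 1]
    return float(base)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a complete synthetic scene; bit-deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    nrows, ncols = grid.shape
    years = list(config.years)
    nyears = len(years)
    ncomp = config.composites_per_year

    # --- epoch masks: threshold one smooth field twice with perturbation ---
    g1 = _smooth_field(rng, nrows, ncols)
    perturb = _smooth_field(rng, nrows, ncols) - 0.5
    thr = np.quantile(g1, 0.45)
    m1 = g1 > thr
    m2 = (g1 + 0.12 * perturb) > thr
    stable = m1 & m2
    if stable.sum() < max(config.n_sites, 4):
        # degenerate draw: fall back to the first-epoch mask for both
        m2 = m1.copy()
        stable = m1
    mask1 = Raster.from_bool(grid, m1)
    mask2 = Raster.from_bool(grid, m2)

    # --- climate anomalies and July coupling -------------------------------
    params = config.climate_trend_params
    anomalies = {
        "tmean": rng.normal(0.0, params["tmean"]["anomaly_sd"], (nyears, 12)),
    }
    anomalies["tmax"] = anomalies["tmean"] + rng.normal(
        0.0, params["tmax"]["anomaly_sd"], (nyears, 12))
    anomalies["tmin"] = anomalies["tmean"] - np.abs(
        rng.normal(0.0, params["tmin"]["anomaly_sd"], (nyears, 12)))
    # precip anomalies are multiplicative lognormal factors (median 1)
    anomalies["precip"] = np.exp(
        params["precip"]["lognorm_sigma"] * rng.standard_normal((nyears, 12)))
    july_anomaly = anomalies["tmean"][:, 6].copy()
    # the AGB coupling uses the July anomaly with its realized linear
    # component projected out, so the injected trend field *is* the exact
    # least-squares trend of latent AGB (the stored truth stays an oracle)
    t_idx = np.arange(nyears, dtype=float)
    t_c = t_idx - t_idx.mean()
    coupling_anom = july_anomaly - july_anomaly.mean() - (
        (july_anomaly @ t_c) / (t_c @ t_c)) * t_c

    spatial = {
        "tmean": (0.5 - _smooth_field(rng, nrows, ncols)) * params["tmean"]["spatial_range"],
        "precip": (_smooth_field(rng, nrows, ncols) - 0.5) * 2 * params["precip"]["spatial_frac"],
    }
    spatial["tmax"] = spatial["tmean"] + 0.3 * (_smooth_field(rng, nrows, ncols) - 0.5)
    spatial["tmin"] = spatial["tmean"] - 0.3 * (_smooth_field(rng, nrows, ncols) - 0.5)

    # --- latent AGB and NDVI -----------------------------------------------
    # agb_base_range describes marsh productivity, so the base field is
    # normalised over the stable-mask pixels: the marsh itself always spans
    # the configured biomass gradient regardless of where the mask fell
    u = _smooth_field(rng, nrows, ncols)
    u_lo, u_hi = u[stable].min(), u[stable].max()
    u = np.clip((u - u_lo) / max(u_hi - u_lo, 1e-12), 0.0, 1.0)
    base = config.agb_base_range[0] + (
        config.agb_base_range[1] - config.agb_base_range[0]
    ) * u
    trend = np.broadcast_to(np.asarray(config.agb_trend, dtype=float),
                            (nrows, ncols)).copy()
    y_mid = float(np.mean(years))
    year_off = np.asarray(years, dtype=float) - y_mid
    latent = (base[None, :, :]
              + trend[None, :, :] * year_off[:, None, None]
              + config.july_coupling * coupling_anom[:, None, None])
    latent = np.clip(latent, *config.agb_clip)

    ndvi_peak = np.power(latent / config.true_a, 1.0 / config.true_b)
    ndvi_winter = 0.05
    c_idx = np.arange(ncomp) + 0.5
    season = np.sin(np.pi * c_idx / ncomp) ** 2       # exact 1.0 mid-year (odd ncomp)
    ndvi = (ndvi_winter
            + (ndvi_peak[:, None, :, :] - ndvi_winter) * season[None, :, None, None])
    if config.ndvi_noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, config.ndvi_noise_sd, ndvi.shape)
    ndvi = np.clip(ndvi, -0.2, 1.0)

    # --- stations ------------------------------------------------------------
    xmin, xmax, ymin, ymax = grid.extent
    sx = rng.uniform(xmin + 0.02 * (xmax - xmin), xmax - 0.02 * (xmax - xmin),
                     config.n_stations)
    sy = rng.uniform(ymin + 0.02 * (ymax - ymin), ymax - 0.02 * (ymax - ymin),
                     config.n_stations)
    stations = []
    month_idx = pd.MultiIndex.from_product([years, range(1, 13)],
                                           names=["year", "month"])
    for k in range(config.n_stations):
        row = min(int((grid.origin_y - sy[k]) // grid.pixel_size), nrows - 1)
        col = min(int((sx[k] - grid.origin_x) // grid.pixel_size), ncols - 1)
        data = {v: [] for v in ("precip_mm", "tmin_c", "tmax_c", "tmean_c")}
        for yi, year in enumerate(years):
            for m in range(1, 13):
                for var, colname in (("precip", "precip_mm"), ("tmin", "tmin_c"),
                                     ("tmax", "tmax_c"), ("tmean", "tmean_c")):
                    det = _climate_deterministic(config, var, year, m)
                    if var == "precip":
                        v = (det * (1.0 + spatial["precip"][row, col])
                             * anomalies["precip"][yi, m - 1])
                    else:
                        v = det + spatial[var][row, col] + anomalies[var][yi, m - 1]
                    data[colname].append(v)
        series = pd.DataFrame(data, index=month_idx)
        # enforce tmin <= tmean <= tmax pixelwise (anomaly draws are small
        # relative to the ±6 °C offsets, so this rarely binds)
        series["tmax_c"] = np.maximum(series["tmax_c"], series["tmean_c"])
        series["tmin_c"] = np.minimum(series["tmin_c"], series["tmean_c"])
        stations.append(StationRecord(station_id=f"S{k:02d}", x=float(sx[k]),
                                      y=float(sy[k]), series=series))

    # --- field sites ----------------------------------------------------------
    # stratify site placement across the biomass gradient (one site per
    # base-AGB quantile bin), emulating a calibration campaign that samples
    # the full range of marsh productivity rather than a random patch
    stable_idx = np.flatnonzero(stable.ravel())
    order = stable_idx[np.argsort(base.ravel()[stable_idx])]
    bins = np.array_split(order, config.n_sites)
    chosen = np.array([rng.choice(b) for b in bins if len(b)])
    if len(chosen) < config.n_sites:  # tiny masks: fall back to random picks
        extra = rng.choice(stable_idx, size=config.n_sites - len(chosen),
                           replace=False)
        chosen = np.concatenate([chosen, extra])
    site_year_pool = sorted(set(config.site_years) & set(years))
    sigma = float(np.sqrt(np.log1p(config.agb_noise_cv**2)))
    sites = []
    for k, flat in enumerate(chosen):
        r_i, c_i = divmod(int(flat), ncols)
        cx, cy = grid.center_of(r_i, c_i)
        jitter = rng.uniform(-0.25, 0.25, 2) * grid.pixel_size
        year = site_year_pool[k % len(site_year_pool)]
        yi = years.index(year)
        latent_site = latent[yi, r_i, c_i]
        dry = latent_site / CARBON_FRACTION
        mult = np.exp(sigma * rng.standard_normal(3)) if sigma > 0 else np.ones(3)
        quadrats = tuple(float(dry * m) for m in mult)
        sites.append(SampleSite(site_id=f"P{k:02d}", x=float(cx + jitter[0]),
                                y=float(cy + jitter[1]), year=year,
                                quadrat_biomass=quadrats))

    truth = SceneTruth(
        true_a=config.true_a, true_b=config.true_b, trend_field=trend,
        base_field=base, latent_agb=latent, ndvi_peak=ndvi_peak,
        july_anomaly=july_anomaly, july_coupling=config.july_coupling,
        climate_spatial=spatial, climate_anomaly=anomalies,
        climate_params=dict(config.climate_trend_params),
    )
    return SyntheticScene(config=config, mask_epoch1=mask1, mask_epoch2=mask2,
                          ndvi_composites=ndvi, stations=stations, sites=sites,
                          truth=truth)


def truth_expected_trend(scene: SyntheticScene, pixel: tuple[int, int]) -> float:
    """The generating linear AGB trend (g·C/m²/a) at a stable-mask pixel."""
    r, c = pixel
    stable = scene.mask_epoch1.as_bool() & scene.mask_epoch2.as_bool()
    if not (0 <= r < scene.grid.nrows and 0 <= c < scene.grid.ncols) or not stable[r, c]:
        raise ValueError(f"pixel {pixel} is outside the stable marsh mask")
    return float(scene.truth.trend_field[r, c])


def generate_calibration_pairs(n: int, true_a: float, true_b: float, cv: float,
                               rng: np.random.Generator,
                               ndvi_range: tuple[float, float] = (0.55, 0.95),
                               ) -> np.ndarray:
    """(NDVI_max, AGB density) pairs from the power law with lognormal noise.

    The multiplicative noise has median 1 and coefficient of variation
    ``cv``; with cv=0 the pairs lie exactly on the curve.
    """
    x = rng.uniform(*ndvi_range, n)
    y = true_a * np.power(x, true_b)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        y = y * np.exp(sigma * rng.standard_normal(n))
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# scene export (masks/NDVI as ASCII grids, stations/sites CSV, truth JSON)
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, str]:
    """Write a scene to disk in the exchange layout the pipeline can re-read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_mask_ascii(scene.mask_epoch1, out / "mask_epoch1.asc")
    write_mask_ascii(scene.mask_epoch2, out / "mask_epoch2.asc")
    paths["mask_epoch1"] = str(out / "mask_epoch1.asc")
    paths["mask_epoch2"] = str(out / "mask_epoch2.asc")
    ndvi_dir = out / "ndvi"
    ndvi_dir.mkdir(exist_ok=True)
    for yi, year in enumerate(scene.config.years):
        for c in range(scene.ndvi_composites.shape[1]):
            write_ascii_grid(Raster(scene.grid, scene.ndvi_composites[yi, c]),
                             ndvi_dir / f"ndvi_{year}_{c:02d}.asc", fmt="%.4f")
    paths["ndvi_dir"] = str(ndvi_dir)
    write_stations_csv(scene.stations, out / "stations.csv")
    write_sites_csv(scene.sites, out / "sites.csv")
    paths["stations"] = str(out / "stations.csv")
    paths["sites"] = str(out / "sites.csv")
    truth = {
        "true_a": scene.truth.true_a,
        "true_b": scene.truth.true_b,
        "july_coupling": scene.truth.july_coupling,
        "july_anomaly": scene.truth.july_anomaly.tolist(),
        "trend_field": scene.truth.trend_field.tolist(),
        "climate_params": scene.truth.climate_params,
    }
    (out / "truth.json").write_text(json.dumps(truth) + "\n")
    paths["truth"] = str(out / "truth.json")
    (out / "config.json").write_text(json.dumps(_config_to_jsonable(scene.config),
                                                indent=2) + "\n")
    paths["config"] = str(out / "config.json")
    return paths


def _config_to_jsonable(config: SceneConfig) -> dict:
    d = asdict(config)
    d["years"] = list(config.years)
    d["site_years"] = list(config.site_years)
    d["agb_trend"] = (config.agb_trend.tolist()
                      if isinstance(config.agb_trend, np.ndarray)
                      else float(config.agb_trend))
    return d
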