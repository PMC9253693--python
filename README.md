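# marshagb

Estimating marsh aboveground biomass (AGB) carbon and its climate drivers
from satellite greenness. The package implements, as a fully tested
pipeline, the standard remote-sensing workflow for herbaceous wetland
carbon monitoring:

1. **Stable marsh mask** — intersect two epoch marsh-extent maps so only
   pixels that stayed marsh through the whole period are analysed.
2. **Maximum-value compositing (MVC)** — reduce 16-day NDVI composites to
   each pixel's annual maximum `NDVI_max`, the peak-greenness proxy for
   standing biomass.
3. **Power-law calibration** — from field sites (three 1 m² quadrats each,
   dry mass × 0.45 → carbon density) fit

   `AGB density = a · NDVI_max^b  [g·C/m²]`

   against the site pixel's `NDVI_max`, competing the power form against
   linear, exponential and logarithmic alternatives by R² on the AGB
   scale, and validating with RMSE and mean relative error.
4. **Mapping and aggregation** — apply the model per pixel and year over
   the stable mask; aggregate to regional mean density and total carbon
   stock (Tg·C).
5. **Trend analysis** — the per-pixel least-squares slope
   `θ_slope = (n·Σ i·y_i − Σi·Σy_i) / (n·Σi² − (Σi)²)` of the annual AGB
   series, with t-test significance (n−2 df).
6. **Climate correlation** — ordinary kriging (spherical variogram) of
   monthly station precipitation and temperatures onto the analysis grid,
   then Pearson correlation of the regional AGB series with every
   monthly/annual climate series (a 13 × 4 table with p<0.05 / p<0.01
   flags), per-pixel correlation maps, and a split of the table south and
   north of the 47°N parallel.

Because no observational data ship with the package, a first-class
synthetic-scene generator (`marshagb.synthetic`) emulates all four inputs —
masks, NDVI stacks, station climate, field quadrats — from a seeded random
stream with a known generating power law, a known injected AGB trend and a
known July-temperature coupling, so every stage can be verified against
ground truth.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic scene (100×100 pixels at 250 m, 21 years × 23 composites,
21 stations, 16 sites; generating truth `a = 643.57`, `b = 4.2474`,
injected trend 2.47 g·C/m²/a):

```sh
python analysis/01_simulate_scene.py      # scene -> scratch/scene
python analysis/02_calibrate_agb_model.py # fit + select the model
python analysis/03_agb_trends.py          # AGB maps, carbon stock, trends
python analysis/04_climate_correlations.py# kriging + correlation tables
```

At seed 0 the calibration stage prints:

```
Calibrated on 16 sites (seed 0).
  power        R²= 0.884  a=   618.126  b= 4.1693 <- selected
  exponential  R²= 0.882  a=     4.479  b= 4.9898
  linear       R²= 0.866  a=  1346.007  b=-822.4976
  logarithmic  R²= 0.852  a=   498.300  b=1075.2091
Selected model: AGB = 618.13 · NDVI_max^4.1693
Validation: RMSE=30.64 g·C/m², relative error=7.69% (generating truth: a=643.57, b=4.2474)
```

i.e. with 16 sites and 15% multiplicative observation noise the power form
wins the R² competition and its parameters land within ~4% of the
generating truth. The trend stage then reports

```
Long-term mean AGB density: 289.79 g·C/m² over 3.14e+08 m² -> total 0.0911 Tg·C.
Regional trend: 2.422 g·C/m²/a (p=0.0012); trend-map median 2.436 vs injected 2.47 g·C/m²/a.
```

— the regional carbon stock follows directly from mean density × marsh
area × 10⁻¹², and the pixelwise trend map recovers the injected slope
within ~1.5%. The correlation stage prints the 13 × 4 table; the July
temperature cells (r ≈ 0.63–0.72, p<0.01) are the strongest positive
entries of their columns, exactly as constructed, while annual
precipitation stays weak.

## Library surface

```python
import marshagb as m

scene = m.generate_scene(m.SceneConfig(seed=0))
report = m.run_pipeline(m.RunConfig(out_dir="out", scene=m.SceneConfig(seed=0), seed=0))
report.summary["model"]          # selected form, a, b, R², RMSE, rel. error
report.summary["regional"]       # mean density, area, total Tg·C
report.summary["trend"]          # regional slope, p, trend-map median
report.summary["correlation_table"]
```

Individual stages (`stable_marsh_mask`, `annual_ndvi_max`, `site_ndvi_max`,
`fit_candidates`, `select_best`, `predict_raster`, `regional_summary`,
`krige_field`, `theta_slope`, `pearson_r`, `pixelwise_map`,
`correlation_table`, `latitude_split`, …) are importable directly; see
`docs/methods.md` for the model assumptions and numerical choices.
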