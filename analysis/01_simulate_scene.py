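#!/usr/bin/env python
"""Generate the synthetic study scene and export it for the later stages.

Builds the default observed-data-shaped scene — a 100×100 pixel 250 m
grid, 21 years (2000–2020) of 23 sixteen-day NDVI composites, two epoch
marsh masks, 21 climate stations and 16 field sites — with the published
power law (643.57 · NDVI_max^4.2474) as the generating truth and a uniform
injected AGB trend of 2.47 g·C/m²/a.  The full scene (rasters included)
goes to scratch/; a small provenance summary goes to results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from marshagb import SceneConfig, generate_scene
from marshagb.synthetic import write_scene


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--scene-dir", type=Path, default=Path("scratch/scene"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SceneConfig(seed=args.seed)
    scene = generate_scene(cfg)
    paths = write_scene(scene, args.scene_dir)

    stable = scene.mask_epoch1.as_bool() & scene.mask_epoch2.as_bool()
    info = {
        "seed": args.seed,
        "grid": f"{cfg.nrows}x{cfg.ncols} @ {cfg.pixel_size} m",
        "years": [cfg.years[0], cfg.years[-1]],
        "stable_marsh_pixels": int(stable.sum()),
        "stable_marsh_fraction": round(float(stable.mean()), 4),
        "n_sites": len(scene.sites),
        "n_stations": len(scene.stations),
        "true_power_law": {"a": cfg.true_a, "b": cfg.true_b},
        "injected_trend_gC_m2_a": float(np.asarray(cfg.agb_trend).mean()),
        "scene_dir": str(args.scene_dir),
    }
    args.results.mkdir(parents=True, exist_ok=True)
    (args.results / "scene_info.json").write_text(json.dumps(info, indent=2) + "\n")

    print(f"Scene written to {args.scene_dir} ({len(paths)} artifact groups).")
    print(f"Stable marsh covers {info['stable_marsh_fraction']:.1%} of the grid "
          f"({info['stable_marsh_pixels']} pixels of {cfg.pixel_size} m).")
    print(f"Truth: AGB = {cfg.true_a} · NDVI_max^{cfg.true_b}, "
          f"trend {info['injected_trend_gC_m2_a']} g·C/m²/a, "
          f"July coupling {cfg.july_coupling} g·C/m² per °C.")


if __name__ == "__main__":
    main()
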