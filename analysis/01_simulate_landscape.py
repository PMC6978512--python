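"""Generate the synthetic study landscape and summarize what it contains.

Writes the full input bundle (structure rasters in both tree-size
variants, six years of mortality polygons, DEM, roads, zones, reference
loss raster, ground truth) under scratch/bundle/ and a one-row landscape
summary under results/.
"""

from pathlib import Path

import pandas as pd

from sdbiomass.synthetic import LandscapeConfig, generate_bundle, write_bundle

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = LandscapeConfig(seed=SEED)
    bundle = generate_bundle(config, reference_noise_sd_log=0.5)
    write_bundle(bundle, ROOT / "scratch" / "bundle")

    up, lo = bundle.structure_upper, bundle.structure_lower
    summary = pd.DataFrame(
        [
            {
                "grid": f"{config.spec.n_rows}x{config.spec.n_cols} @ {config.spec.pixel_size} m",
                "forest_pixels": int(up.forest_mask.sum()),
                "mortality_polygons": len(bundle.polygons),
                "years": len(config.years),
                "total_dead_trees": round(sum(p.dead_trees for p in bundle.polygons), 1),
                "true_dead_biomass_bdt": round(float(bundle.truth.tdbm.sum()), 1),
                "mean_tph_upper": round(float(up.tph[up.forest_mask].mean()), 1),
                "mean_tph_lower": round(float(lo.tph[lo.forest_mask].mean()), 1),
            }
        ]
    )
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summary.to_csv(out / "landscape_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nbundle written to {ROOT / 'scratch' / 'bundle'}")


if __name__ == "__main__":
    main()
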