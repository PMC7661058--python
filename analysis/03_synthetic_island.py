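#!/usr/bin/env python
"""Generate the Elba-scale synthetic island used by the spatial analyses.

The real vegetation map behind the original study is not redistributable,
so the spatial stages run on a generated stand-in of the same magnitudes:
~224 km2 of land, macchia-dominant woodland with oak and a chestnut pocket,
29 coastal smelting sites carrying the packaged catalogue's windows and
slag bounds, and twelve angular regions.  Writes the rasters (ESRI ASCII)
and site catalogue to results/island/.
"""

import warnings
from pathlib import Path

from elbawood.landscape import CLASS_CODES, growth_curves, standing_stock
from elbawood.config import default_config
from elbawood.sites import write_sites
from elbawood.synthetic import elba_like_spec, make_island, place_sites

OUT = Path(__file__).resolve().parents[1] / "results" / "island"
RESOLUTION = 250.0   # m; working resolution of the desk-scale analyses
SEED = 5


def main() -> None:
    spec = elba_like_spec(resolution=RESOLUTION, seed=SEED)
    landscape = make_island(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sites, _ = place_sites(landscape, spec)

    OUT.mkdir(parents=True, exist_ok=True)
    landscape.save(OUT)
    write_sites(sites, OUT / "sites.csv")

    config = default_config()
    stock = standing_stock(landscape, growth_curves(config),
                           config["specific_gravity"])
    land_km2 = landscape.land.sum() * landscape.cell_area_ha / 100
    print(f"island: {landscape.shape[0]}x{landscape.shape[1]} cells at "
          f"{RESOLUTION:.0f} m ({land_km2:.0f} km2 land)")
    for name, code in CLASS_CODES.items():
        share = (landscape.veg == code).sum() / landscape.land.sum()
        print(f"  {name:9s} {share:5.1%} of land")
    print(f"initial mature standing stock: {stock.sum() / 1e6:.2f} Mt dry wood")
    print(f"{len(sites)} coastal sites; wrote rasters and sites.csv to {OUT}")


if __name__ == "__main__":
    main()
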