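"""Simulate the synthetic study region.

Generates a 30x30 bimodal-rainfall region (Tanzania-like latitudes, long
rains peaking March-May and short rains October-December, annual totals
750-1200 mm) covering 2000-2021, with coupled NDVI and a land-cover mask,
and writes the four rasters under results/data/.  Every later analysis step
reads from there, so one seed here fixes the whole study.
"""

import argparse
from pathlib import Path

from plantwin import (
    SyntheticSpec,
    generate_climate_fields,
    generate_landcover,
    generate_ndvi,
    write_cube,
    write_mask,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    spec = SyntheticSpec(n_rows=30, n_cols=30, years=(2000, 2021),
                         regime="bimodal", seed=args.seed)
    rain, temp = generate_climate_fields(spec)
    ndvi = generate_ndvi(rain, temp, spec)
    mask = generate_landcover(spec)

    args.out.mkdir(parents=True, exist_ok=True)
    write_cube(rain, args.out / "rainfall.nc")
    write_cube(temp, args.out / "temperature.nc")
    write_cube(ndvi, args.out / "ndvi.nc")
    write_mask(mask, args.out / "landcover.nc")

    n_water = int(mask.water.sum())
    print(f"simulated {rain.n_time} months on a 30x30 grid (seed {args.seed})")
    print(f"land cover: {n_water} water, {int(mask.cropland.sum())} cropland, "
          f"{900 - n_water - int(mask.cropland.sum())} other land cells")
    print(f"wrote rainfall/temperature/ndvi/landcover to {args.out}")


if __name__ == "__main__":
    main()
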