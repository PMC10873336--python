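"""Map per-window planting suitability.

Builds the twelve 4-month moving planting windows (October-January through
September-December, with October-December starts wrapping from the first
year range) over the simulated region, thresholds each window's seasonal
rainfall total against 300-1600 mm and its mean temperature against
17-34 degC (the sunflower requirement ranges), AND-combines the two layers,
masks water, and writes one Boolean map per window under results/maps/.
"""

import argparse
from pathlib import Path

from plantwin import (
    Variable,
    aggregate_window,
    build_windows,
    combine_suitability,
    default_crop_parameters,
    read_cube,
    read_mask,
    threshold_suitability,
)
from plantwin.pipeline import write_cube_like_map


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/maps"))
    args = parser.parse_args()

    rain = read_cube(args.data / "rainfall.nc", Variable.RAINFALL)
    temp = read_cube(args.data / "temperature.nc", Variable.TEMPERATURE)
    mask = read_mask(args.data / "landcover.nc")
    params = default_crop_parameters()
    y0 = rain.time_axis[0][0]
    windows = build_windows(first_range=(y0, y0 + 1), second_range=(y0 + 1, y0 + 2))

    args.out.mkdir(parents=True, exist_ok=True)
    for window in windows:
        rain_layer = threshold_suitability(
            aggregate_window(rain, window, "sum"),
            params.rain_season_min, params.rain_season_max,
        )
        temp_layer = threshold_suitability(
            aggregate_window(temp, window, "mean"), params.temp_min, params.temp_max,
        )
        combined = combine_suitability([rain_layer, temp_layer], mask)
        slug = window.label.lower().replace("-", "_")
        write_cube_like_map(combined, args.out / f"suitability_{slug}.nc")
        n_suit = int(combined.suitable.sum())
        print(f"{window.label:<22} {n_suit:>4} suitable cells")
    print(f"wrote 12 Boolean suitability maps to {args.out}")


if __name__ == "__main__":
    main()
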