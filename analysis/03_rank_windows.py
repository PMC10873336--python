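"""Rank the planting windows by suitable share of the land.

For every window map: count suitable pixels, convert to area and to the
percent of the (water-excluded) land area, min-max normalize the suitable
and non-suitable percentages onto [0, 1], and rank windows from most to
least suitable.  Writes results/season_ranking.csv — the table behind a
mirrored/radial seasonal-suitability chart.
"""

import argparse
from pathlib import Path

from plantwin import build_windows, cell_area_grid, rank_windows, read_mask, suitable_percent
from plantwin.rio import read_static, write_table
from plantwin.suitability import SuitabilityMap


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--maps", type=Path, default=Path("results/maps"))
    parser.add_argument("--out", type=Path, default=Path("results/season_ranking.csv"))
    args = parser.parse_args()

    mask = read_mask(args.data / "landcover.nc")
    areas = cell_area_grid(mask.geometry, mode="uniform")
    windows = {w.label: w for w in build_windows()}

    summaries = []
    for path in sorted(args.maps.glob("suitability_*.nc")):
        values, geom, name = read_static(path)
        label = name.removeprefix("suitability_")
        smap = SuitabilityMap(geometry=geom, window=windows[label], values=values)
        summaries.append(suitable_percent(smap, areas, mask))

    table = rank_windows(summaries)
    write_table(table, args.out)
    print(table[["window", "suitable_percent", "z_suitable", "rank"]].to_string(index=False))
    top, bottom = table.iloc[0], table.iloc[-1]
    print(f"\nmost suitable window: {top['window']} ({top['suitable_percent']:.2f}% of land)")
    print(f"least suitable window: {bottom['window']} ({bottom['suitable_percent']:.2f}%)")


if __name__ == "__main__":
    main()
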