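"""Moving planting-season windows and window aggregation.

A planting window is a fixed-length run of consecutive calendar months
(default four, matching a 90–160-day crop cycle) anchored to a start month.
Twelve windows — one per start month — cover the year.  Windows starting in
October, November, or December wrap into the following calendar year and are
assigned to the earlier of the two year ranges of the analysis; windows
starting January through September are assigned to the later range.  This
reproduces a growing season that straddles the year boundary: aggregating on
single calendar years would mix two distinct seasons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ClimateCube, GridGeometry, Variable, month_name

__all__ = ["PlantingWindow", "SeasonalGrid", "build_windows", "aggregate_window"]

#: start months assigned to the earlier year range (they wrap into the next year)
FIRST_RANGE_START_MONTHS = (10, 11, 12)


@dataclass(frozen=True)
class PlantingWindow:
    """A labeled run of consecutive calendar months, possibly wrapping the year.

    ``year_pair`` is (start_year, end_year): months <= 12 - length + start
    fall in start_year and any wrapped months in end_year.
    """

    label: str
    start_month: int
    length_months: int
    wraps_year: bool
    year_pair: tuple[int, int]

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month must be in 1..12, got {self.start_month}")
        if not 1 <= self.length_months <= 12:
            raise ValueError(f"length_months must be in 1..12, got {self.length_months}")
        wraps = self.start_month + self.length_months - 1 > 12
        if wraps != self.wraps_year:
            raise ValueError(
                f"wraps_year={self.wraps_year} inconsistent with start month "
                f"{self.start_month} and length {self.length_months}"
            )
        if self.wraps_year and self.year_pair[1] != self.year_pair[0] + 1:
            raise ValueError("a wrapping window needs consecutive years in year_pair")

    @property
    def months(self) -> tuple[int, ...]:
        """Calendar month numbers covered, in window order."""
        return tuple((self.start_month - 1 + k) % 12 + 1 for k in range(self.length_months))

    @property
    def end_month(self) -> int:
        return self.months[-1]

    def year_months(self) -> tuple[tuple[int, int], ...]:
        """(year, month) pairs covered, strictly increasing in calendar time."""
        start_year = self.year_pair[0]
        out = []
        year = start_year
        prev = None
        for m in self.months:
            if prev is not None and m < prev:
                year += 1
            out.append((year, m))
            prev = m
        return tuple(out)

    def with_year_pair(self, year_pair: tuple[int, int]) -> "PlantingWindow":
        return PlantingWindow(
            label=self.label,
            start_month=self.start_month,
            length_months=self.length_months,
            wraps_year=self.wraps_year,
            year_pair=year_pair,
        )


def make_window(start_month: int, year_pair: tuple[int, int], length_months: int = 4) -> PlantingWindow:
    """Build one window from its start month and assigned year pair."""
    wraps = start_month + length_months - 1 > 12
    end_month = (start_month - 1 + length_months - 1) % 12 + 1
    label = f"{month_name(start_month)}-{month_name(end_month)}"
    return PlantingWindow(
        label=label,
        start_month=start_month,
        length_months=length_months,
        wraps_year=wraps,
        year_pair=year_pair,
    )


def build_windows(
    length_months: int = 4,
    first_range: tuple[int, int] = (2000, 2001),
    second_range: tuple[int, int] = (2001, 2002),
    first_range_start_months: tuple[int, ...] = FIRST_RANGE_START_MONTHS,
) -> list[PlantingWindow]:
    """Build the twelve moving windows for two consecutive year ranges.

    Windows starting in ``first_range_start_months`` (default Oct/Nov/Dec)
    take ``first_range`` as their year pair; all others take
    ``second_range``.  Returned in calendar order of the production year:
    October-January first, September-December last.
    """
    if not 1 <= length_months <= 12:
        raise ValueError(f"length_months must be in 1..12, got {length_months}")
    if first_range[1] != first_range[0] + 1 or second_range[1] != second_range[0] + 1:
        raise ValueError("each year range must be a consecutive (y, y+1) pair")
    if second_range[0] != first_range[0] + 1:
        raise ValueError(
            f"year ranges must be sequential, got {first_range} then {second_range}"
        )
    order = list(first_range_start_months) + [
        m for m in range(1, 13) if m not in first_range_start_months
    ]
    windows = []
    for start in order:
        year_pair = first_range if start in first_range_start_months else second_range
        windows.append(make_window(start, year_pair, length_months))
    return windows


@dataclass
class SeasonalGrid:
    """Per-cell aggregate of one variable over one window.

    ``statistic`` is "sum" (rainfall totals, comparable to a seasonal
    requirement in mm) or "mean" (temperature, NDVI).
    """

    geometry: GridGeometry
    window: PlantingWindow
    variable: Variable
    statistic: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.variable = Variable(self.variable)
        if self.statistic not in ("sum", "mean"):
            raise ValueError(f"statistic must be 'sum' or 'mean', got {self.statistic!r}")
        if self.statistic == "sum" and self.variable is not Variable.RAINFALL:
            raise ValueError(
                f"statistic='sum' is only meaningful for rainfall, not {self.variable.value}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )


def default_statistic(variable: Variable | str) -> str:
    """Window statistic used by the pipeline: rainfall summed, others averaged."""
    return "sum" if Variable(variable) is Variable.RAINFALL else "mean"


def aggregate_window(
    cube: ClimateCube,
    window: PlantingWindow,
    statistic: str | None = None,
) -> SeasonalGrid:
    """Aggregate a monthly cube over one window's (year, month) span.

    NoData in any contributing month propagates to NoData in the output
    (conservative masking).  ``statistic`` defaults per variable: sum for
    rainfall, mean otherwise.
    """
    if statistic is None:
        statistic = default_statistic(cube.variable)
    if statistic == "sum" and cube.variable is not Variable.RAINFALL:
        raise ValueError(
            f"statistic='sum' requested for {cube.variable.value}; only rainfall is summed"
        )
    idx = [cube.time_index(y, m) for y, m in window.year_months()]
    stack = cube.values[idx]  # (length_months, rows, cols); NaN propagates below
    agg = stack.sum(axis=0) if statistic == "sum" else stack.mean(axis=0)
    return SeasonalGrid(
        geometry=cube.geometry,
        window=window,
        variable=cube.variable,
        statistic=statistic,
        values=agg,
    )
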