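"""NDVI-climate correlation over planting windows.

For each window and year a spatial-mean series is built (rainfall summed
over the window, temperature and NDVI averaged, then averaged over land
cells), and the Pearson coefficient between a climate series and NDVI is
computed from the raw-sums form

    r = [n Σxy − Σx Σy] / sqrt([n Σx² − (Σx)²][n Σy² − (Σy)²]).

Strength is classified on |r|: [0, 0.20) very weak, [0.20, 0.40) weak,
[0.40, 0.60) moderate, [0.60, 0.80) strong, [0.80, 1] very strong — bins
half-open at the break points so no value falls in a gap.  Significance is a
two-sided t test with t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ClimateCube, LandMask, Variable
from .windows import PlantingWindow, aggregate_window, default_statistic

__all__ = [
    "Strength",
    "SeasonalSeries",
    "CorrelationResult",
    "seasonal_series",
    "pearson_r",
    "classify_strength",
    "correlation_pvalue",
    "load_reference_series",
]


class Strength(str, enum.Enum):
    VERY_WEAK = "very weak"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very strong"


@dataclass
class SeasonalSeries:
    """Per-year spatial-mean of one variable over one window."""

    window: PlantingWindow
    variable: Variable
    years: tuple[int, ...]
    values: np.ndarray
    mask_used: str = "land"

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years),):
            raise ValueError("years and values must have equal length")


@dataclass
class CorrelationResult:
    r: float
    n: int
    strength: Strength
    sign: str
    p_value: float | None = None


def seasonal_series(
    cube: ClimateCube,
    window: PlantingWindow,
    years: list[int],
    mask: LandMask | None = None,
    area_weights: np.ndarray | None = None,
) -> SeasonalSeries:
    """Window aggregate then spatial mean over land, one value per year.

    Each requested year re-anchors the window at (year, year+1).  Water
    cells are excluded; pass ``area_weights`` (e.g. a cosine-latitude area
    grid) for an area-weighted rather than simple mean.
    """
    statistic = default_statistic(cube.variable)
    include = np.ones(cube.geometry.shape, dtype=bool)
    if mask is not None:
        mask.require_same_geometry(cube.geometry)
        include = mask.land
    if not include.any():
        raise ValueError("land mask excludes every cell")
    weights = np.ones(cube.geometry.shape) if area_weights is None else np.asarray(area_weights, float)
    values = []
    for year in years:
        grid = aggregate_window(cube, window.with_year_pair((year, year + 1)), statistic)
        cells = include & np.isfinite(grid.values)
        if not cells.any():
            raise ValueError(f"no valid land cells for {window.label} in {year}")
        w = weights[cells]
        values.append(float(np.sum(grid.values[cells] * w) / np.sum(w)))
    return SeasonalSeries(
        window=window,
        variable=cube.variable,
        years=tuple(years),
        values=np.array(values),
        mask_used="land" if mask is not None else "all-cells",
    )


def pearson_r(x, y, with_pvalue: bool = False) -> CorrelationResult:
    """Pearson correlation from the raw-sums formula, with strength class.

    Requires two equal-length, non-constant series of n >= 3 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    den_x = n * sxx - sx * sx
    den_y = n * syy - sy * sy
    if den_x <= 0 or den_y <= 0:
        raise ValueError("constant series: correlation undefined")
    r = (n * sxy - sx * sy) / np.sqrt(den_x * den_y)
    r = float(np.clip(r, -1.0, 1.0))  # guard rounding spill past ±1
    sign = "positive" if r > 0 else ("negative" if r < 0 else "zero")
    p = correlation_pvalue(r, n) if with_pvalue else None
    return CorrelationResult(r=r, n=n, strength=classify_strength(r), sign=sign, p_value=p)


_BINS = (
    (0.20, Strength.VERY_WEAK),
    (0.40, Strength.WEAK),
    (0.60, Strength.MODERATE),
    (0.80, Strength.STRONG),
)


def classify_strength(r: float) -> Strength:
    """Strength class of |r|; boundary values belong to the upper bin."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for upper, label in _BINS:
        if a < upper:
            return label
    return Strength.VERY_STRONG


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0, via the t transform on n-2 df.

    |r| = 1 returns 0.0 (the degenerate limit).  Symmetric in the sign of r.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def load_reference_series() -> pd.DataFrame:
    """Published Tanzania seasonal-mean series (2000-2020, 5-year step).

    Columns: window, year, rainfall_mm, temperature_c, ndvi — the
    January-April and June-September spatial means used for the
    NDVI-climate correlations.
    """
    with resources.as_file(
        resources.files("plantwin.data") / "tanzania_seasonal_means.csv"
    ) as p:
        return pd.read_csv(p)
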