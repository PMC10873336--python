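"""Suitable-area accounting, normalization, and window ranking.

For each window the suitable fraction of the land area is

    e = 100 * (area of suitable cells) / (total land area),

with water excluded from both numerator and denominator.  On a uniform grid
the suitable area reduces to a (pixel area) times b (suitable pixel count).
The per-window percentages are min-max normalized,

    z_i = (x_i - min x) / (max x - min x),

onto [0, 1] for both the suitable and non-suitable series so the two can be
presented on one mirrored or radial scale, and windows are ranked by e
descending.

The historically printed form of the percentage, e = (a*b)/d * 1e6 (with the
stated intent of converting m^2 to km^2), is dimensionally a ratio times a
constant rather than a percent of land; it is retained behind
``formula="literal"`` for auditability, but the default is the percent form
that the reported per-window values are consistent with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridGeometry, LandMask
from .suitability import SuitabilityMap

__all__ = [
    "SeasonSummary",
    "cell_area_grid",
    "suitable_percent",
    "minmax_normalize",
    "rank_windows",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class SeasonSummary:
    """Per-window area accounting.

    Attributes follow the bookkeeping of the area equation: ``a`` mean pixel
    area (m^2), ``b`` suitable pixel count, ``c`` suitable area (m^2),
    ``d`` total land area (m^2), ``e`` percent of land suitable.  The
    normalized scores and rank are filled by :func:`rank_windows`.
    """

    window_label: str
    start_month: int
    a: float
    b: int
    c: float
    d: float
    e: float
    nonsuitable_percent: float
    z_suitable: float = np.nan
    z_nonsuitable: float = np.nan
    rank: int = 0


def cell_area_grid(
    geometry: GridGeometry,
    mode: str = "uniform",
    uniform_area_m2: float = 1_000_000.0,
) -> np.ndarray:
    """Per-cell surface area in m^2.

    ``uniform`` returns the supplied constant everywhere.  ``cosine_lat``
    returns the spherical quadrangle approximation
    (R dlat) * (R dlon cos(lat_center)) per row, so cell area shrinks toward
    the poles as cos(latitude).
    """
    if geometry.cell_size <= 0:
        raise ValueError("cell size must be positive")
    if mode == "uniform":
        if uniform_area_m2 <= 0:
            raise ValueError("uniform cell area must be positive")
        return np.full(geometry.shape, float(uniform_area_m2))
    if mode == "cosine_lat":
        dlat = np.deg2rad(geometry.cell_size)
        dlon = np.deg2rad(geometry.cell_size)
        lat = np.deg2rad(geometry.lat_centers())
        row_area = (EARTH_RADIUS_M * dlat) * (EARTH_RADIUS_M * dlon) * np.cos(lat)
        return np.repeat(row_area[:, None], geometry.n_cols, axis=1)
    raise ValueError(f"unknown area mode {mode!r}; use 'uniform' or 'cosine_lat'")


def suitable_percent(
    smap: SuitabilityMap,
    areas: np.ndarray,
    mask: LandMask | None = None,
    include_water_in_denominator: bool = False,
    formula: str = "percent",
) -> SeasonSummary:
    """Suitable/non-suitable area bookkeeping for one window.

    Water (NoData) cells are excluded from numerator and denominator unless
    ``include_water_in_denominator``.  With unequal cell areas the suitable
    area is the sum of areas over suitable cells, which reduces to a*b on a
    uniform grid.  ``formula="literal"`` reports e as (a*b)/d * 1e6 instead
    of the percent form.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.shape != smap.geometry.shape:
        raise ValueError(f"area grid shape {areas.shape} != geometry {smap.geometry.shape}")
    if formula not in ("percent", "literal"):
        raise ValueError(f"unknown formula {formula!r}; use 'percent' or 'literal'")

    counted = np.isfinite(smap.values)
    if mask is not None:
        mask.require_same_geometry(smap.geometry)
        counted &= mask.land
        if include_water_in_denominator:
            counted = np.isfinite(smap.values) | mask.water
    suitable = smap.suitable & counted

    d = float(areas[counted].sum())
    if d <= 0:
        raise ValueError("zero countable land area")
    b = int(suitable.sum())
    c = float(areas[suitable].sum())
    a = float(areas[counted].mean())
    if formula == "percent":
        e = 100.0 * c / d
        non = 100.0 * (d - c) / d
    else:
        e = (a * b) / d * 1_000_000.0
        non = (d - c) / d * 1_000_000.0
    window = smap.window
    return SeasonSummary(
        window_label=window.label if window is not None else "",
        start_month=window.start_month if window is not None else 0,
        a=a,
        b=b,
        c=c,
        d=d,
        e=e,
        nonsuitable_percent=non,
    )


def minmax_normalize(values) -> np.ndarray:
    """Min-max rescale onto [0, 1]: z_i = (x_i - min) / (max - min).

    Order-preserving and invariant to affine rescaling of the input.  A
    degenerate all-equal input returns all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("all values equal; min-max normalization degenerate, returning zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def rank_windows(summaries: list[SeasonSummary]) -> pd.DataFrame:
    """Rank windows by suitable percent, descending; fill normalized scores.

    Rank 1 is the most suitable window; ties break toward the earlier start
    month in calendar order.  Returns the ranked table (one row per window)
    and mutates the summaries' ``z_suitable``, ``z_nonsuitable`` and ``rank``
    in place.
    """
    labels = [s.window_label for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate window labels in summaries")
    if len(summaries) == 1:  # nothing to rescale against
        z_s = z_n = np.zeros(1)
    else:
        z_s = minmax_normalize([s.e for s in summaries])
        z_n = minmax_normalize([s.nonsuitable_percent for s in summaries])
    order = sorted(
        range(len(summaries)),
        key=lambda i: (-summaries[i].e, summaries[i].start_month),
    )
    for pos, i in enumerate(order, start=1):
        summaries[i].rank = pos
        summaries[i].z_suitable = float(z_s[i])
        summaries[i].z_nonsuitable = float(z_n[i])
    rows = [
        {
            "window": s.window_label,
            "start_month": s.start_month,
            "suitable_pixels": s.b,
            "suitable_area_km2": s.c / 1e6,
            "suitable_percent": s.e,
            "nonsuitable_percent": s.nonsuitable_percent,
            "z_suitable": s.z_suitable,
            "z_nonsuitable": s.z_nonsuitable,
            "rank": s.rank,
        }
        for s in sorted(summaries, key=lambda s: s.rank)
    ]
    return pd.DataFrame(rows)
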