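"""Boolean planting-season suitability layers and their combination.

Each seasonal grid is thresholded against a closed requirement interval into
a {1, 0} layer; layers are AND-combined into the final suitable /
not-suitable map.  Water cells are excluded from the analysis altogether —
they become NoData, never 0 — while an optional cropland restriction forces
non-cropland land to 0.  Static terrain/soil criteria (slope, elevation, pH,
soil depth) form an extra opt-in layer; the default combination uses
rainfall and temperature only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridGeometry, LandMask
from .rio import CropParameters
from .windows import PlantingWindow, SeasonalGrid

__all__ = [
    "SuitabilityMap",
    "threshold_suitability",
    "static_environment_mask",
    "combine_suitability",
]


@dataclass
class SuitabilityMap:
    """Per-cell {1 suitable, 0 not suitable, NaN excluded} grid.

    ``provenance`` names the layers that produced the map, e.g.
    ``["rainfall[300,1600]", "temperature[17,34]"]``.
    """

    geometry: GridGeometry
    window: PlantingWindow | None
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        finite = self.values[np.isfinite(self.values)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("suitability values must be 1, 0, or NaN")

    @property
    def suitable(self) -> np.ndarray:
        return self.values == 1.0

    @property
    def excluded(self) -> np.ndarray:
        return ~np.isfinite(self.values)


def threshold_suitability(grid: SeasonalGrid, lower: float, upper: float) -> SuitabilityMap:
    """1 where ``lower <= value <= upper`` (closed interval), else 0; NaN kept.

    Closed at both ends: a seasonal rainfall total of exactly 300 mm meets a
    [300, 1600] mm requirement.
    """
    if lower > upper:
        raise ValueError(f"lower > upper: ({lower}, {upper})")
    vals = grid.values
    out = np.where((vals >= lower) & (vals <= upper), 1.0, 0.0)
    out[~np.isfinite(vals)] = np.nan
    return SuitabilityMap(
        geometry=grid.geometry,
        window=grid.window,
        values=out,
        provenance=[f"{grid.variable.value}[{lower},{upper}]"],
    )


#: static criterion name -> (CropParameters attributes, predicate builder)
_STATIC_CRITERIA = ("slope", "elevation", "ph", "soil_depth")


def static_environment_mask(
    env_grids: dict[str, np.ndarray],
    params: CropParameters,
    geometry: GridGeometry,
) -> SuitabilityMap:
    """AND of the supplied static terrain/soil criteria.

    Recognised grids: ``slope`` (%), ``elevation`` (m), ``ph``,
    ``soil_depth`` (cm).  Unsupplied criteria are ignored; supplying a grid
    whose parameter range is unset is an error.  With no grids at all the
    result is the identity (all-1) layer.
    """
    out = np.ones(geometry.shape)
    provenance: list[str] = []
    for name, grid in env_grids.items():
        if name not in _STATIC_CRITERIA:
            raise ValueError(f"unknown static criterion {name!r}; expected one of {_STATIC_CRITERIA}")
        grid = np.asarray(grid, dtype=float)
        if grid.shape != geometry.shape:
            raise ValueError(f"{name} grid shape {grid.shape} != geometry {geometry.shape}")
        if name == "slope":
            if params.slope_max is None:
                raise ValueError("slope grid supplied but slope_max parameter unset")
            ok = grid <= params.slope_max
            provenance.append(f"slope<= {params.slope_max}")
        elif name == "elevation":
            if params.elevation_max is None:
                raise ValueError("elevation grid supplied but elevation_max parameter unset")
            ok = grid <= params.elevation_max
            provenance.append(f"elevation<= {params.elevation_max}")
        elif name == "ph":
            if params.ph_min is None or params.ph_max is None:
                raise ValueError("ph grid supplied but ph range parameters unset")
            ok = (grid >= params.ph_min) & (grid <= params.ph_max)
            provenance.append(f"ph[{params.ph_min},{params.ph_max}]")
        else:  # soil_depth
            if params.soil_depth_min is None or params.soil_depth_max is None:
                raise ValueError("soil_depth grid supplied but soil depth range unset")
            ok = (grid >= params.soil_depth_min) & (grid <= params.soil_depth_max)
            provenance.append(f"soil_depth[{params.soil_depth_min},{params.soil_depth_max}]")
        layer = np.where(ok, 1.0, 0.0)
        layer[~np.isfinite(grid)] = np.nan
        out = out * layer  # AND with NaN propagation
    return SuitabilityMap(geometry=geometry, window=None, values=out, provenance=provenance)


def combine_suitability(
    layers: list[SuitabilityMap],
    mask: LandMask | None = None,
    restrict_to_cropland: bool = False,
) -> SuitabilityMap:
    """Logical AND across layers, then apply the land-cover mask.

    Water cells are forced to NaN (excluded from all downstream area
    accounting); with ``restrict_to_cropland`` non-cropland land cells are
    forced to 0.  NoData in any layer propagates.
    """
    if not layers:
        raise ValueError("need at least one suitability layer")
    geometry = layers[0].geometry
    window = layers[0].window
    out = np.ones(geometry.shape)
    provenance: list[str] = []
    for layer in layers:
        if layer.geometry != geometry:
            raise ValueError("suitability layers have mismatched geometries")
        out = out * layer.values  # AND; NaN propagates
        provenance.extend(layer.provenance)
        if window is None:
            window = layer.window
    if mask is not None:
        mask.require_same_geometry(geometry)
        out[mask.water] = np.nan
        provenance.append("water=NoData")
        if restrict_to_cropland:
            out[mask.land & ~mask.cropland] = 0.0
            provenance.append("cropland-only")
    return SuitabilityMap(geometry=geometry, window=window, values=out, provenance=provenance)
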