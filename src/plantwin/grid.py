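"""Core gridded containers: geometry, monthly climate cubes, land-cover masks.

The internal grid convention is north-up: row 0 is the northernmost row and
cell centers sit at ``bound + (i + 0.5) * cell_size``.  Every module in the
package shares this convention.  NoData is represented internally as NaN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "GridGeometry",
    "Variable",
    "ClimateCube",
    "LandClass",
    "LandMask",
    "month_name",
    "MONTH_NAMES",
]

MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


def month_name(month: int) -> str:
    """Full English name for a 1-based month number."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return MONTH_NAMES[month - 1]


@dataclass(frozen=True)
class GridGeometry:
    """Regular geographic grid in degrees, north-up.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    lat_bounds
        (south, north) in degrees.
    lon_bounds
        (west, east) in degrees.
    cell_size
        Cell edge length in degrees (square cells).
    """

    n_rows: int
    n_cols: int
    lat_bounds: tuple[float, float]
    lon_bounds: tuple[float, float]
    cell_size: float

    def __post_init__(self) -> None:
        south, north = self.lat_bounds
        west, east = self.lon_bounds
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if south >= north:
            raise ValueError(f"lat_bounds must satisfy south < north, got {self.lat_bounds}")
        if west >= east:
            raise ValueError(f"lon_bounds must satisfy west < east, got {self.lon_bounds}")
        if abs(self.n_rows * self.cell_size - (north - south)) > self.cell_size:
            raise ValueError(
                "n_rows * cell_size does not span lat_bounds within one cell"
            )
        if abs(self.n_cols * self.cell_size - (east - west)) > self.cell_size:
            raise ValueError(
                "n_cols * cell_size does not span lon_bounds within one cell"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Per-row latitude of cell centers, row 0 northernmost."""
        _, north = self.lat_bounds
        return north - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        west, _ = self.lon_bounds
        return west + (np.arange(self.n_cols) + 0.5) * self.cell_size


class Variable(str, enum.Enum):
    """Climate variables handled by the pipeline, with canonical units."""

    RAINFALL = "rainfall"
    TEMPERATURE = "temperature"
    NDVI = "ndvi"

    @property
    def units(self) -> str:
        return _UNITS[self]


_UNITS = {
    Variable.RAINFALL: "mm/month",
    Variable.TEMPERATURE: "degC",
    Variable.NDVI: "unitless",
}


def _check_time_axis(time_axis: tuple[tuple[int, int], ...]) -> None:
    if len(time_axis) == 0:
        raise ValueError("time axis is empty")
    for year, month in time_axis:
        if not 1 <= month <= 12:
            raise ValueError(f"invalid month {month} in time axis")
    for (y0, m0), (y1, m1) in zip(time_axis, time_axis[1:]):
        expect = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
        if (y1, m1) != expect:
            raise ValueError(
                f"time axis not contiguous monthly: {y0}-{m0:02d} followed by "
                f"{y1}-{m1:02d} (expected {expect[0]}-{expect[1]:02d})"
            )


@dataclass
class ClimateCube:
    """Monthly gridded variable with units and NaN NoData.

    ``values`` has shape ``(n_time, n_rows, n_cols)`` aligned with
    ``time_axis``, an ordered tuple of (year, month) pairs that must be
    contiguous in calendar time.
    """

    geometry: GridGeometry
    variable: Variable
    time_axis: tuple[tuple[int, int], ...]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.variable = Variable(self.variable)
        if not self.units:
            self.units = self.variable.units
        elif self.units != self.variable.units:
            raise ValueError(
                f"units {self.units!r} conflict with variable "
                f"{self.variable.value!r} (expected {self.variable.units!r})"
            )
        self.time_axis = tuple((int(y), int(m)) for y, m in self.time_axis)
        _check_time_axis(self.time_axis)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.time_axis), *self.geometry.shape)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (time, rows, cols) {expected}"
            )
        self._validate_range()

    def _validate_range(self) -> None:
        vals = self.values
        if self.variable is Variable.RAINFALL:
            bad = np.nonzero(vals < 0)
            label = "rainfall < 0 mm"
        elif self.variable is Variable.NDVI:
            bad = np.nonzero((vals < -1) | (vals > 1))
            label = "NDVI outside [-1, 1]"
        else:
            return
        if bad[0].size:
            t, i, j = bad[0][0], bad[1][0], bad[2][0]
            year, month = self.time_axis[t]
            raise ValueError(
                f"{label}: value {vals[t, i, j]} at cell (row {i}, col {j}) "
                f"in {year}-{month:02d}"
            )

    @property
    def n_time(self) -> int:
        return len(self.time_axis)

    def time_index(self, year: int, month: int) -> int:
        """Index along the time axis of (year, month)."""
        try:
            return self.time_axis.index((year, month))
        except ValueError:
            raise KeyError(
                f"cube does not cover {year}-{month:02d} "
                f"(spans {self.time_axis[0]} .. {self.time_axis[-1]})"
            ) from None

    def sel(self, year: int, month: int) -> np.ndarray:
        """2-D field for one calendar month."""
        return self.values[self.time_index(year, month)]

    def to_xarray(self) -> xr.DataArray:
        """View as an xarray.DataArray with time/lat/lon coordinates."""
        time = [np.datetime64(f"{y}-{m:02d}", "M") for y, m in self.time_axis]
        return xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={
                "time": np.asarray(time, dtype="datetime64[M]").astype("datetime64[ns]"),
                "lat": self.geometry.lat_centers(),
                "lon": self.geometry.lon_centers(),
            },
            name=self.variable.value,
            attrs={"units": self.units},
        )


class LandClass(enum.IntEnum):
    """Land-cover classes used for masking."""

    WATER = 0
    LAND = 1
    CROPLAND = 2


@dataclass
class LandMask:
    """Categorical land-cover grid over {water, land, cropland}."""

    geometry: GridGeometry
    classes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.shape != self.geometry.shape:
            raise ValueError(
                f"classes shape {self.classes.shape} != geometry {self.geometry.shape}"
            )
        valid = np.isin(self.classes, [int(c) for c in LandClass])
        if not valid.all():
            i, j = np.nonzero(~valid)
            raise ValueError(
                f"unknown land-cover class {self.classes[i[0], j[0]]} "
                f"at cell (row {i[0]}, col {j[0]})"
            )

    @property
    def water(self) -> np.ndarray:
        return self.classes == LandClass.WATER

    @property
    def land(self) -> np.ndarray:
        """All non-water cells (plain land plus cropland)."""
        return self.classes != LandClass.WATER

    @property
    def cropland(self) -> np.ndarray:
        return self.classes == LandClass.CROPLAND

    def require_same_geometry(self, other_geometry: GridGeometry) -> None:
        if other_geometry != self.geometry:
            raise ValueError("mask geometry does not match companion grid")
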