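"""Raster and parameter-file I/O.

Two container dialects are supported and map onto the same in-memory
:class:`~plantwin.grid.ClimateCube`:

* a NetCDF cube (``.nc``) with an integer month-index time coordinate,
  written through xarray's scipy backend (NetCDF3, text-free environment
  friendly), and
* a multi-band TIFF (``.tif``/``.tiff``) with one band per month and the
  geometry, variable, and "YYYY-MM" band labels stored as JSON in the image
  description tag.

Crop-requirement ranges are read from a nested YAML file; the packaged
``data/sunflower.yaml`` holds the FAO ECOCROP-derived sunflower defaults.
Tabular outputs are written as CSV with units spelled out in the header.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr
import yaml

from .grid import ClimateCube, GridGeometry, LandMask, Variable

__all__ = [
    "CropParameters",
    "load_crop_parameters",
    "default_crop_parameters",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "write_table",
]


# --------------------------------------------------------------------------
# crop parameters


@dataclass(frozen=True)
class CropParameters:
    """Crop requirement ranges used to threshold seasonal grids.

    Climate requirements (seasonal rainfall total in mm, mean temperature in
    degC, growth-cycle length in days) are mandatory; terrain and soil
    criteria are optional and only enforced when the matching static grid is
    supplied to the suitability engine.
    """

    rain_season_min: float
    rain_season_max: float
    temp_min: float
    temp_max: float
    cycle_min: float
    cycle_max: float
    slope_max: float | None = None          # %
    elevation_max: float | None = None      # m
    elevation_well_suited: float | None = None  # m
    ph_min: float | None = None
    ph_max: float | None = None
    salinity_max: float | None = None       # dS/m
    bulk_density: float | None = None       # g/cm^3
    soil_water_content: float | None = None  # %
    soil_depth_min: float | None = None     # cm
    soil_depth_max: float | None = None     # cm

    def __post_init__(self) -> None:
        for lo_name, hi_name in [
            ("rain_season_min", "rain_season_max"),
            ("temp_min", "temp_max"),
            ("cycle_min", "cycle_max"),
            ("ph_min", "ph_max"),
            ("soil_depth_min", "soil_depth_max"),
        ]:
            lo, hi = getattr(self, lo_name), getattr(self, hi_name)
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{lo_name} > {hi_name}: ({lo}, {hi})")
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")

    @property
    def has_soil(self) -> bool:
        return self.ph_min is not None or self.soil_depth_min is not None


_RANGE_KEYS = {
    "rain_season_mm": ("rain_season_min", "rain_season_max"),
    "temp_c": ("temp_min", "temp_max"),
    "cycle_days": ("cycle_min", "cycle_max"),
    "ph": ("ph_min", "ph_max"),
    "soil_depth_cm": ("soil_depth_min", "soil_depth_max"),
}
_SCALAR_KEYS = {
    "slope_max_percent": "slope_max",
    "elevation_max_m": "elevation_max",
    "elevation_well_suited_m": "elevation_well_suited",
    "salinity_max_ds_m": "salinity_max",
    "bulk_density_g_cm3": "bulk_density",
    "soil_water_content_percent": "soil_water_content",
}


def load_crop_parameters(path: str | Path) -> CropParameters:
    """Load crop requirement ranges from a nested YAML file.

    Unknown keys raise a warning rather than an error; an omitted ``soil``
    or ``terrain`` block leaves the corresponding criteria unset so the
    suitability engine skips them.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs: dict[str, float] = {}
    for block_name in ("climate", "terrain", "soil"):
        block = doc.get(block_name) or {}
        for key, value in block.items():
            if key in _RANGE_KEYS:
                lo_name, hi_name = _RANGE_KEYS[key]
                lo, hi = float(value[0]), float(value[1])
                kwargs[lo_name] = lo
                kwargs[hi_name] = hi
            elif key in _SCALAR_KEYS:
                kwargs[_SCALAR_KEYS[key]] = float(value)
            else:
                warnings.warn(f"unknown crop-parameter key {block_name}.{key!r}; ignored")
    for key in doc:
        if key not in ("crop", "climate", "terrain", "soil"):
            warnings.warn(f"unknown crop-parameter block {key!r}; ignored")
    missing = {"rain_season_min", "temp_min", "cycle_min"} - kwargs.keys()
    if missing:
        raise ValueError(f"crop-parameter file lacks mandatory climate ranges: {sorted(missing)}")
    return CropParameters(**kwargs)


def default_crop_parameters() -> CropParameters:
    """The packaged sunflower requirement ranges."""
    with resources.as_file(resources.files("plantwin.data") / "sunflower.yaml") as p:
        return load_crop_parameters(p)


# --------------------------------------------------------------------------
# cubes


def _geometry_meta(geom: GridGeometry) -> dict:
    return {
        "n_rows": geom.n_rows,
        "n_cols": geom.n_cols,
        "lat_bounds": list(geom.lat_bounds),
        "lon_bounds": list(geom.lon_bounds),
        "cell_size": geom.cell_size,
    }


def _geometry_from_meta(meta: dict) -> GridGeometry:
    return GridGeometry(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        lat_bounds=tuple(meta["lat_bounds"]),
        lon_bounds=tuple(meta["lon_bounds"]),
        cell_size=float(meta["cell_size"]),
    )


def write_cube(cube: ClimateCube, path: str | Path) -> Path:
    """Write a cube to NetCDF (``.nc``) or multi-band TIFF (``.tif``).

    Full float64 precision is preserved, so a write/read round trip is
    lossless; NaN is the NoData sentinel in both dialects.
    """
    path = Path(path)
    meta = {
        "variable": cube.variable.value,
        "units": cube.units,
        "time_axis": [f"{y}-{m:02d}" for y, m in cube.time_axis],
        "geometry": _geometry_meta(cube.geometry),
    }
    if path.suffix == ".nc":
        month_index = [y * 12 + (m - 1) for y, m in cube.time_axis]
        da = xr.DataArray(
            cube.values,
            dims=("month_index", "lat", "lon"),
            coords={
                "month_index": np.asarray(month_index, dtype=np.int32),
                "lat": cube.geometry.lat_centers(),
                "lon": cube.geometry.lon_centers(),
            },
            name=cube.variable.value,
            attrs={"units": cube.units, "plantwin_meta": json.dumps(meta)},
        )
        da.to_dataset().to_netcdf(path, engine="scipy")
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, cube.values, description=json.dumps(meta),
                         photometric="minisblack")
    else:
        raise ValueError(f"unsupported raster dialect {path.suffix!r} (use .nc or .tif)")
    return path


def _parse_time_labels(labels: list[str]) -> tuple[tuple[int, int], ...]:
    axis = []
    for lab in labels:
        year, month = lab.split("-")
        axis.append((int(year), int(month)))
    return tuple(axis)


def read_cube(path: str | Path, variable: str | Variable | None = None) -> ClimateCube:
    """Read a cube written by :func:`write_cube`, validating all invariants.

    ``variable``, when given, must match the variable recorded in the file.
    """
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            name = list(ds.data_vars)[0]
            da = ds[name].load()
        meta = json.loads(da.attrs["plantwin_meta"])
        values = np.asarray(da.values, dtype=float)
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            meta = json.loads(tf.pages[0].description)
            values = tf.asarray().astype(float)
        if values.ndim == 2:
            values = values[None, :, :]
    else:
        raise ValueError(f"unsupported raster dialect {path.suffix!r} (use .nc or .tif)")
    file_var = Variable(meta["variable"])
    if variable is not None and Variable(variable) is not file_var:
        raise ValueError(
            f"requested variable {Variable(variable).value!r} but file stores {file_var.value!r}"
        )
    return ClimateCube(
        geometry=_geometry_from_meta(meta["geometry"]),
        variable=file_var,
        time_axis=_parse_time_labels(meta["time_axis"]),
        values=values,
    )


# --------------------------------------------------------------------------
# masks


def write_mask(mask: LandMask, path: str | Path) -> Path:
    path = Path(path)
    meta = {"kind": "landmask", "geometry": _geometry_meta(mask.geometry)}
    if path.suffix == ".nc":
        da = xr.DataArray(
            mask.classes.astype(np.int16),
            dims=("lat", "lon"),
            coords={"lat": mask.geometry.lat_centers(), "lon": mask.geometry.lon_centers()},
            name="landcover",
            attrs={"plantwin_meta": json.dumps(meta)},
        )
        da.to_dataset().to_netcdf(path, engine="scipy")
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.classes.astype(np.int16), description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported raster dialect {path.suffix!r} (use .nc or .tif)")
    return path


def read_mask(path: str | Path) -> LandMask:
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            da = ds["landcover"].load()
        meta = json.loads(da.attrs["plantwin_meta"])
        classes = np.asarray(da.values)
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            meta = json.loads(tf.pages[0].description)
            classes = tf.asarray()
    else:
        raise ValueError(f"unsupported raster dialect {path.suffix!r} (use .nc or .tif)")
    return LandMask(geometry=_geometry_from_meta(meta["geometry"]), classes=classes)


# --------------------------------------------------------------------------
# static single-band grids (slope, elevation, pH, soil depth)


def write_static(values: np.ndarray, geometry: GridGeometry, name: str, path: str | Path) -> Path:
    """Write a single-band static grid (e.g. slope %, elevation m)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.shape:
        raise ValueError(f"values shape {values.shape} != geometry {geometry.shape}")
    meta = {"kind": "static", "name": name, "geometry": _geometry_meta(geometry)}
    if path.suffix == ".nc":
        da = xr.DataArray(
            values,
            dims=("lat", "lon"),
            coords={"lat": geometry.lat_centers(), "lon": geometry.lon_centers()},
            name=name,
            attrs={"plantwin_meta": json.dumps(meta)},
        )
        da.to_dataset().to_netcdf(path, engine="scipy")
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, values, description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported raster dialect {path.suffix!r} (use .nc or .tif)")
    return path


def read_static(path: str | Path) -> tuple[np.ndarray, GridGeometry, str]:
    """Read a static grid written by :func:`write_static`."""
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            name = list(ds.data_vars)[0]
            da = ds[name].load()
        meta = json.loads(da.attrs["plantwin_meta"])
        values = np.asarray(da.values, dtype=float)
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            meta = json.loads(tf.pages[0].description)
            values = tf.asarray().astype(float)
    else:
        raise ValueError(f"unsupported raster dialect {path.suffix!r} (use .nc or .tif)")
    return values, _geometry_from_meta(meta["geometry"]), meta.get("name", "static")


# --------------------------------------------------------------------------
# tables


def write_table(df, path: str | Path) -> Path:
    """Write a summary table as CSV (column names carry their units)."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path
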