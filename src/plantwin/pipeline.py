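"""End-to-end orchestration: synth -> windows -> suitability -> rank -> correlate.

One :class:`RunConfig` (usually loaded from YAML) drives the whole analysis
and every artifact lands under one output directory together with a run
manifest (inputs, parameters, seed, package version, SHA-256 of each
output), so identical config + seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .correlate import pearson_r, seasonal_series
from .grid import ClimateCube, LandMask, Variable
from .ranking import cell_area_grid, rank_windows, suitable_percent
from .rio import (
    CropParameters,
    default_crop_parameters,
    load_crop_parameters,
    read_cube,
    read_mask,
    read_static,
    write_cube,
    write_mask,
    write_table,
)
from .suitability import combine_suitability, static_environment_mask, threshold_suitability
from .synth import NoiseSpec, SyntheticSpec, generate_climate_fields, generate_landcover, generate_ndvi
from .windows import PlantingWindow, aggregate_window, build_windows

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("plantwin")


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run.

    Exactly one of ``synth`` (synthetic-data spec overrides) or ``inputs``
    (paths to rainfall/temperature/ndvi cubes and the land mask) must be
    given.
    """

    out_dir: Path
    seed: int = 0
    synth: dict | None = None
    inputs: dict | None = None
    crop_params_path: Path | None = None
    calendar: dict = field(default_factory=dict)
    engine: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)
    raster_format: str = "nc"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'synth' or 'inputs'")
        if self.inputs is not None:
            for key in ("rainfall", "temperature", "ndvi", "mask"):
                p = self.inputs.get(key)
                if p is None or not Path(p).exists():
                    raise ValueError(f"inputs.{key} missing or not found: {p}")
        if self.crop_params_path is not None and not Path(self.crop_params_path).exists():
            raise ValueError(f"crop parameter file not found: {self.crop_params_path}")
        if self.raster_format not in ("nc", "tif"):
            raise ValueError("raster_format must be 'nc' or 'tif'")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(
        out_dir=doc.get("out_dir", "plantwin_out"),
        seed=int(doc.get("seed", 0)),
        synth=doc.get("synth"),
        inputs=doc.get("inputs"),
        crop_params_path=doc.get("crop_params"),
        calendar=doc.get("calendar", {}),
        engine=doc.get("engine", {}),
        correlation=doc.get("correlation", {}),
        raster_format=doc.get("raster_format", "nc"),
        log_level=doc.get("log_level", "INFO"),
    )


def _build_synth_spec(overrides: dict, seed: int) -> SyntheticSpec:
    kwargs = dict(overrides)
    noise = kwargs.pop("noise_sd", None)
    if noise is not None:
        kwargs["noise_sd"] = NoiseSpec(**noise) if isinstance(noise, dict) else noise
    for key in ("lat_bounds", "lon_bounds", "years", "annual_rain_range", "temp_mean_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    kwargs.setdefault("seed", seed)
    return SyntheticSpec(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_year_spec(text: str) -> list[int]:
    """Parse "start:end:step" into the inclusive sampled year list."""
    start, end, step = (int(p) for p in text.split(":"))
    return list(range(start, end + 1, step))


def _select_windows(windows: list[PlantingWindow], labels) -> list[PlantingWindow]:
    if labels in (None, "all"):
        return windows
    by_label = {w.label: w for w in windows}
    missing = [lab for lab in labels if lab not in by_label]
    if missing:
        raise ValueError(f"unknown window labels {missing}; have {sorted(by_label)}")
    return [by_label[lab] for lab in labels]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to the out dir)."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ext = "." + config.raster_format
    artifacts: dict[str, str] = {}

    def record(path: Path) -> Path:
        artifacts[str(path.relative_to(out))] = _sha256(path)
        return path

    # --- stage 1: inputs -------------------------------------------------
    if config.synth is not None:
        spec = _build_synth_spec(config.synth, config.seed)
        rain, temp = generate_climate_fields(spec)
        ndvi = generate_ndvi(rain, temp, spec)
        mask = generate_landcover(spec)
        record(write_cube(rain, out / f"rainfall{ext}"))
        record(write_cube(temp, out / f"temperature{ext}"))
        record(write_cube(ndvi, out / f"ndvi{ext}"))
        record(write_mask(mask, out / f"landcover{ext}"))
        source = {"kind": "synthetic", "spec_seed": spec.seed, "regime": spec.regime}
    else:
        rain = read_cube(config.inputs["rainfall"], Variable.RAINFALL)
        temp = read_cube(config.inputs["temperature"], Variable.TEMPERATURE)
        ndvi = read_cube(config.inputs["ndvi"], Variable.NDVI)
        mask = read_mask(config.inputs["mask"])
        source = {"kind": "files", **{k: str(v) for k, v in config.inputs.items()}}
    log.info(
        "inputs: %d months on %s grid; %d water / %d land / %d cropland cells",
        rain.n_time, rain.geometry.shape, int(mask.water.sum()),
        int((mask.land & ~mask.cropland).sum()), int(mask.cropland.sum()),
    )

    params = (
        load_crop_parameters(config.crop_params_path)
        if config.crop_params_path is not None
        else default_crop_parameters()
    )

    # --- stage 2: windows ------------------------------------------------
    cal = config.calendar
    y0 = rain.time_axis[0][0]
    first_range = tuple(cal.get("first_range", (y0, y0 + 1)))
    second_range = tuple(cal.get("second_range", (y0 + 1, y0 + 2)))
    windows = build_windows(
        length_months=int(cal.get("length_months", 4)),
        first_range=first_range,
        second_range=second_range,
    )
    selected = _select_windows(windows, config.engine.get("windows"))

    # --- stage 3: suitability --------------------------------------------
    engine = config.engine
    rain_stat = engine.get("rainfall_statistic", "sum")
    restrict = bool(engine.get("restrict_cropland", False))
    env_layer = None
    if engine.get("env_grids"):
        env_grids = {}
        for name, path in engine["env_grids"].items():
            values, geom, _ = read_static(path)
            if geom != rain.geometry:
                raise ValueError(f"static grid {name!r} geometry mismatch")
            env_grids[name] = values
        env_layer = static_environment_mask(env_grids, params, rain.geometry)

    maps = []
    for window in selected:
        rain_grid = aggregate_window(rain, window, rain_stat)
        temp_grid = aggregate_window(temp, window, "mean")
        layers = [
            threshold_suitability(rain_grid, params.rain_season_min, params.rain_season_max),
            threshold_suitability(temp_grid, params.temp_min, params.temp_max),
        ]
        if env_layer is not None:
            layers.append(env_layer)
        combined = combine_suitability(layers, mask, restrict_to_cropland=restrict)
        maps.append(combined)
        slug = window.label.lower().replace("-", "_")
        record(write_cube_like_map(combined, out / f"suitability_{slug}{ext}"))
    log.info("suitability: %d combined window maps", len(maps))

    # --- stage 4: ranking ------------------------------------------------
    area_mode = engine.get("area_mode", "uniform")
    areas = cell_area_grid(rain.geometry, mode=area_mode)
    summaries = [suitable_percent(m, areas, mask) for m in maps]
    table = rank_windows(summaries)
    record(write_table(table, out / "season_ranking.csv"))
    log.info("ranking: top window %s (%.2f%% suitable)",
             table.iloc[0]["window"], table.iloc[0]["suitable_percent"])

    # --- stage 5: correlation --------------------------------------------
    corr_cfg = config.correlation
    corr_labels = corr_cfg.get("windows", ["January-April", "June-September"])
    year_spec = corr_cfg.get("years")
    fixed_years = _parse_year_spec(year_spec) if year_spec is not None else None
    corr_windows = _select_windows(windows, corr_labels)
    covered = set(rain.time_axis)
    rows = []
    years: list[int] = []
    for window in corr_windows:
        if fixed_years is not None:
            years = fixed_years
        else:  # every year whose anchored window the cube fully covers
            all_years = sorted({y for y, _ in rain.time_axis})
            years = [
                y for y in all_years
                if set(window.with_year_pair((y, y + 1)).year_months()) <= covered
            ]
        if len(years) < 3:
            raise ValueError(
                f"correlation for {window.label} needs >= 3 covered years, have {years}"
            )
        nd = seasonal_series(ndvi, window, years, mask)
        for cube, pair in ((rain, "rainfall-ndvi"), (temp, "temperature-ndvi")):
            cl = seasonal_series(cube, window, years, mask)
            res = pearson_r(cl.values, nd.values, with_pvalue=True)
            rows.append({
                "window": window.label, "pair": pair, "n": res.n,
                "r": res.r, "strength": res.strength.value, "p_value": res.p_value,
            })
    import pandas as pd

    corr_table = pd.DataFrame(rows)
    record(write_table(corr_table, out / "ndvi_climate_correlation.csv"))
    log.info("correlation: %d window/variable pairs", len(rows))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "source": source,
        "calendar": {"first_range": list(first_range), "second_range": list(second_range)},
        "windows": [w.label for w in selected],
        "correlation_years": years,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_cube_like_map(smap, path: Path) -> Path:
    """Persist a suitability map as a single-band static raster."""
    from .rio import write_static

    label = smap.window.label if smap.window is not None else "static"
    return write_static(smap.values, smap.geometry, f"suitability_{label}", path)
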