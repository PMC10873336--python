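"""Seeded synthetic gridded climate: rainfall, temperature, NDVI, land cover.

The generator emulates the structure of East-African monthly climate that
the suitability analysis assumes, so every downstream stage is testable
without satellite downloads:

* rainfall with a unimodal (one wet season) or bimodal (long rains centered
  on March-May, short rains centered on October-December) monthly
  climatology, annual cell totals drawn within a configurable range
  (defaults 750-1200 mm/yr bimodal, 300-2000 mm/yr unimodal) and varying
  smoothly in space and from year to year;
* land-surface temperature smooth in space with a mild seasonal cycle and a
  small negative coupling to the concurrent rainfall anomaly (cloud and
  evaporative cooling make wet years cooler — this is what gives seasonal
  mean temperature an interannual signal opposing rainfall);
* NDVI responding positively to rainfall (optionally lagged; at monthly
  compositing the grass/crop greenness response falls within the month, so
  the default response is concurrent) and negatively to temperature,
  clipped into [-1, 1];
* a categorical land-cover grid with one contiguous water body grown to the
  requested fraction of cells, and a cropland subset of the land.

Everything is driven by a single root seed split per variable; equal
(spec, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ClimateCube, GridGeometry, LandClass, LandMask, Variable

__all__ = [
    "NoiseSpec",
    "SyntheticSpec",
    "generate_climate_fields",
    "generate_ndvi",
    "generate_landcover",
]

#: climatological peak months for the two rain seasons (long rains MAM,
#: short rains OND)
LONG_RAINS_PEAK = 4
SHORT_RAINS_PEAK = 11


@dataclass(frozen=True)
class NoiseSpec:
    """Per-variable noise standard deviations.

    Rainfall noise is a multiplicative Gaussian factor truncated at zero
    (keeps dry months dry and totals non-negative); temperature and NDVI
    noise are additive.
    """

    rainfall: float = 0.10      # relative (fraction of the monthly value)
    temperature: float = 0.30   # degC
    ndvi: float = 0.02          # NDVI units

    def __post_init__(self) -> None:
        if min(self.rainfall, self.temperature, self.ndvi) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study region.

    ``years`` is an inclusive (first, last) calendar-year range; cubes cover
    January of the first through December of the last year.  The grid's
    cell size is derived from the latitude span; the eastern longitude bound
    follows from the western bound and the column count (square cells).
    """

    n_rows: int = 30
    n_cols: int = 30
    lat_bounds: tuple[float, float] = (-12.0, -1.0)
    lon_bounds: tuple[float, float] = (29.0, 41.0)
    years: tuple[int, int] = (2000, 2002)
    regime: str = "bimodal"
    annual_rain_range: tuple[float, float] | None = None
    temp_mean_range: tuple[float, float] = (20.0, 30.0)
    rain_ndvi_gain: float = 0.0015   # NDVI per mm of monthly rainfall
    temp_ndvi_gain: float = -0.05    # NDVI per degC of temperature anomaly
    ndvi_base: float = 0.25
    ndvi_lag_months: int = 0
    temp_rain_coupling: float = -0.01  # degC per mm monthly rainfall anomaly
    temp_seasonal_amp: float = 1.5     # degC
    noise_sd: NoiseSpec = field(default_factory=NoiseSpec)
    water_fraction: float = 0.08
    cropland_fraction: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.regime not in ("unimodal", "bimodal"):
            raise ValueError(f"regime must be 'unimodal' or 'bimodal', got {self.regime!r}")
        if self.years[1] < self.years[0]:
            raise ValueError(f"empty year range {self.years}")
        lo, hi = self.rain_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid annual_rain_range ({lo}, {hi})")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError(f"water_fraction must be in [0, 1], got {self.water_fraction}")
        if not 0.0 <= self.cropland_fraction <= 1.0:
            raise ValueError("cropland_fraction must be in [0, 1]")
        if self.rain_ndvi_gain < 0:
            raise ValueError("rain_ndvi_gain must be >= 0")
        if self.temp_ndvi_gain > 0:
            raise ValueError("temp_ndvi_gain must be <= 0")

    @property
    def rain_range(self) -> tuple[float, float]:
        if self.annual_rain_range is not None:
            return self.annual_rain_range
        return (750.0, 1200.0) if self.regime == "bimodal" else (300.0, 2000.0)

    @property
    def geometry(self) -> GridGeometry:
        south, north = self.lat_bounds
        cell = (north - south) / self.n_rows
        west = self.lon_bounds[0]
        return GridGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            lat_bounds=(south, north),
            lon_bounds=(west, west + self.n_cols * cell),
            cell_size=cell,
        )

    @property
    def time_axis(self) -> tuple[tuple[int, int], ...]:
        y0, y1 = self.years
        return tuple((y, m) for y in range(y0, y1 + 1) for m in range(1, 13))

    @property
    def temp_reference(self) -> float:
        """Reference temperature for the NDVI response (range midpoint)."""
        return 0.5 * (self.temp_mean_range[0] + self.temp_mean_range[1])

    def rngs(self) -> dict[str, np.random.Generator]:
        """Per-variable generators split from the single root seed."""
        names = ("rainfall", "temperature", "ndvi", "landcover")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


# --------------------------------------------------------------------------
# helpers


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 3.0) -> np.ndarray:
    """Smooth random field rescaled exactly onto [0, 1]."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    lo, hi = raw.min(), raw.max()
    if hi == lo:  # degenerate 1x1 grid
        return np.full(shape, 0.5)
    return (raw - lo) / (hi - lo)


def _wrapped_gaussian(months: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Gaussian bump on the circular 12-month year."""
    out = np.zeros_like(months, dtype=float)
    for k in (-12.0, 0.0, 12.0):
        out += np.exp(-0.5 * ((months - mu + k) / sigma) ** 2)
    return out


def monthly_profile(regime: str, long_weight: float = 0.6, sigma: float = 1.2) -> np.ndarray:
    """Climatological month-of-year rainfall fractions (sum to 1).

    Bimodal mixes two wrapped-Gaussian bumps centered on the long-rains
    (April) and short-rains (November) peaks; unimodal keeps only the
    long-rains bump.
    """
    months = np.arange(1, 13, dtype=float)
    if regime == "bimodal":
        p = long_weight * _wrapped_gaussian(months, LONG_RAINS_PEAK, sigma)
        p += (1.0 - long_weight) * _wrapped_gaussian(months, SHORT_RAINS_PEAK, sigma)
    else:
        p = _wrapped_gaussian(months, LONG_RAINS_PEAK, sigma)
    return p / p.sum()


# --------------------------------------------------------------------------
# generators


def generate_climate_fields(spec: SyntheticSpec) -> tuple[ClimateCube, ClimateCube]:
    """Monthly rainfall and temperature cubes over the spec's years.

    Rainfall: per cell and year an annual total is drawn within the regime's
    annual range (smooth in space, independent across years) and spread over
    the months by the regime's climatological profile, then perturbed by
    truncated multiplicative noise.  Temperature: a smooth base field within
    ``temp_mean_range`` plus a mild seasonal cycle, a negative response to
    the concurrent rainfall anomaly, and additive noise.
    """
    rngs = spec.rngs()
    geom = spec.geometry
    shape = geom.shape
    time_axis = spec.time_axis
    n_years = spec.years[1] - spec.years[0] + 1
    lo, hi = spec.rain_range

    profile = monthly_profile(spec.regime)

    rng_rain = rngs["rainfall"]
    annual = np.empty((n_years, *shape))
    # blend a smooth spatial pattern with a per-year scalar so that the
    # domain-mean total genuinely varies between years (wet vs dry years);
    # the convex blend of two [0, 1] draws keeps every total inside the range
    for y in range(n_years):
        u_year = rng_rain.uniform()
        annual[y] = lo + (hi - lo) * (
            0.5 * _smooth_field(rng_rain, shape) + 0.5 * u_year
        )
    rain = np.empty((len(time_axis), *shape))
    for t, (year, month) in enumerate(time_axis):
        rain[t] = annual[year - spec.years[0]] * profile[month - 1]
    clim = np.empty_like(rain)  # noise-free climatology, reused for temperature anomaly
    clim[:] = rain
    if spec.noise_sd.rainfall > 0:
        factor = 1.0 + spec.noise_sd.rainfall * rng_rain.standard_normal(rain.shape)
        rain = rain * np.clip(factor, 0.0, None)

    rng_temp = rngs["temperature"]
    t_lo, t_hi = spec.temp_mean_range
    amp = spec.temp_seasonal_amp
    # keep base + cycle inside the stated mean range
    base = (t_lo + amp) + (t_hi - t_lo - 2 * amp) * _smooth_field(rng_temp, shape)
    months = np.array([m for _, m in time_axis], dtype=float)
    # warm peak just before the long rains (February), cool trough in the dry season
    cycle = amp * np.cos(2.0 * np.pi * (months - 2.0) / 12.0)
    mean_monthly_rain = clim.reshape(n_years, 12, *shape).mean(axis=0)
    temp = np.empty_like(rain)
    for t, (year, month) in enumerate(time_axis):
        anomaly = rain[t] - mean_monthly_rain[month - 1]
        temp[t] = base + cycle[t] + spec.temp_rain_coupling * anomaly
    if spec.noise_sd.temperature > 0:
        temp = temp + spec.noise_sd.temperature * rng_temp.standard_normal(temp.shape)

    rain_cube = ClimateCube(geometry=geom, variable=Variable.RAINFALL, time_axis=time_axis, values=rain)
    temp_cube = ClimateCube(geometry=geom, variable=Variable.TEMPERATURE, time_axis=time_axis, values=temp)
    return rain_cube, temp_cube


def generate_ndvi(
    rainfall: ClimateCube,
    temperature: ClimateCube,
    spec: SyntheticSpec,
) -> ClimateCube:
    """NDVI coupled to rainfall (positively) and temperature (negatively).

        ndvi = clip(base + g_r * rain[t - lag] + g_t * (T - T_ref) + noise, -1, 1)

    with T_ref the midpoint of the temperature range (the reference level is
    absorbed into the base so the default base is itself a realistic NDVI).
    ``lag`` defaults to 0 — a monthly composite already integrates the
    within-month greenness response; set ``ndvi_lag_months`` for delayed
    response.  The first ``lag`` months reuse their own rainfall (edge
    replication).
    """
    if rainfall.geometry != temperature.geometry or rainfall.time_axis != temperature.time_axis:
        raise ValueError("rainfall and temperature cubes must share geometry and time axis")
    rng = spec.rngs()["ndvi"]
    lag = spec.ndvi_lag_months
    shifted = rainfall.values.copy()
    if lag > 0:
        shifted[lag:] = rainfall.values[:-lag]
        shifted[:lag] = rainfall.values[:lag]
    ndvi = (
        spec.ndvi_base
        + spec.rain_ndvi_gain * shifted
        + spec.temp_ndvi_gain * (temperature.values - spec.temp_reference)
    )
    if spec.noise_sd.ndvi > 0:
        ndvi = ndvi + spec.noise_sd.ndvi * rng.standard_normal(ndvi.shape)
    ndvi = np.clip(ndvi, -1.0, 1.0)
    return ClimateCube(
        geometry=rainfall.geometry,
        variable=Variable.NDVI,
        time_axis=rainfall.time_axis,
        values=ndvi,
    )


def generate_landcover(spec: SyntheticSpec) -> LandMask:
    """Categorical {water, land, cropland} grid.

    Water is one contiguous blob grown cell-by-cell from a seeded origin
    until exactly ``round(water_fraction * n_cells)`` cells (a lake, not
    salt-and-pepper).  Of the remaining land, roughly ``cropland_fraction``
    becomes cropland via a smooth-field threshold.
    """
    rng = spec.rngs()["landcover"]
    shape = spec.geometry.shape
    n_cells = shape[0] * shape[1]
    n_water = int(round(spec.water_fraction * n_cells))
    classes = np.full(shape, int(LandClass.LAND), dtype=np.int16)

    if n_water >= n_cells:
        classes[:] = int(LandClass.WATER)
        return LandMask(geometry=spec.geometry, classes=classes)

    if n_water > 0:
        water = np.zeros(shape, dtype=bool)
        origin = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        water[origin] = True
        frontier = {origin}
        while water.sum() < n_water:
            candidates = set()
            for (i, j) in frontier:
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < shape[0] and 0 <= nj < shape[1] and not water[ni, nj]:
                        candidates.add((ni, nj))
            if not candidates:
                break
            ordered = sorted(candidates)
            take = min(len(ordered), n_water - int(water.sum()))
            picks = rng.choice(len(ordered), size=take, replace=False)
            for p in picks:
                water[ordered[p]] = True
            frontier = {ordered[p] for p in picks} | frontier
        classes[water] = int(LandClass.WATER)

    land_cells = classes == int(LandClass.LAND)
    if spec.cropland_fraction > 0 and land_cells.any():
        suit = _smooth_field(rng, shape, sigma=2.0)
        vals = suit[land_cells]
        k = int(round(spec.cropland_fraction * vals.size))
        if k > 0:
            cut = np.sort(vals)[::-1][min(k, vals.size) - 1]
            classes[land_cells & (suit >= cut)] = int(LandClass.CROPLAND)
    return LandMask(geometry=spec.geometry, classes=classes)
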