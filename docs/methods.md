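# Methods

## Scope and data model

The package analyses monthly gridded climate on one shared geometry: a
north-up regular lat/lon grid (row 0 northernmost, cell centers at
`bound + (i + 0.5)·cell_size`). A `ClimateCube` holds one variable
(rainfall mm/month, temperature °C, or unitless NDVI) on a contiguous
monthly time axis; NoData is NaN throughout. Inputs at different native
resolutions must be harmonized to one grid before entering the package —
no reprojection or resampling is attempted here.

Two interchangeable container dialects are supported: NetCDF (via xarray's
scipy backend, NetCDF3) and multi-band TIFF with the geometry and
"YYYY-MM" band labels carried in a JSON description tag. Both round-trip
float64 losslessly, NaN included.

## Planting windows

A window is a run of `length_months` consecutive calendar months (default
4, standing in for a 90–160-day crop cycle; windows are closed month sets,
no day arithmetic). Twelve windows cover the year. Start months
October–December wrap into the following year and take the earlier of the
two configured year ranges; January–September take the later. This
split follows the production-calendar convention that a season belongs to
the year pair it connects, and avoids aggregating two distinct seasons as
one. Aggregation over a window is the per-cell **sum** for rainfall and
**mean** for temperature and NDVI. A seasonal rainfall *total* is what a
requirement like 300–1600 mm refers to; averaging monthly rainfall over
the window would compare a per-month quantity against a per-season range
and misclassify almost everywhere. A `statistic` switch preserves the
mean reading for sensitivity checks. NoData in any contributing month
makes the window output NoData (conservative propagation).

## Suitability

Each seasonal grid is thresholded against a closed interval (boundary
values are suitable; the requirement ranges are stated without boundary
semantics, and closedness keeps widening monotone: enlarging an interval
can only turn 0s into 1s). Layers are combined by logical AND. The
default combination uses rainfall and temperature only; static
terrain/soil criteria (slope ≤ slope_max, elevation ≤ elevation_max, pH
and soil depth in range) and a cropland-extent restriction are opt-in.
The "slope ranging from 8.3 %" requirement is treated as a maximum and is
configurable. Water cells are forced to NoData rather than 0: they are
outside the analysis domain, not unsuitable land, and this choice flows
through to every denominator downstream.

## Area accounting and ranking

The suitable percent of land for a window is
`e = 100 · Σ areas(suitable cells) / Σ areas(land cells)`, water excluded
from both sums (a flag restores the all-cells denominator). On a uniform
grid the numerator reduces to pixel-area × pixel-count. Cell areas come
either from a supplied uniform pixel area or from the spherical quadrangle
approximation `(R·Δlat)·(R·Δlon·cos φ)` per row (R = 6 371 km). A
historically printed form of the percentage, `e = (a·b)/d · 10⁶` with the
stated intent of converting m² to km², is dimensionally a ratio times a
constant rather than a percent; it is kept behind `formula="literal"` for
auditability but the percent form is the default and is what the
suitable/non-suitable = 100 conservation property tests assert.

Both the suitable and non-suitable percent series are min–max normalized
(`z_i = (x_i − min)/(max − min)`; an all-equal series returns zeros with a
warning) so the two can sit on one mirrored/radial scale, and windows are
ranked by descending `e` with ties broken toward the earlier start month —
a deterministic, calendar-meaningful rule.

## NDVI–climate correlation

Per window and year the cube is aggregated over the window anchored at
(year, year+1) and averaged over land cells (area-weighted if a
cosine-latitude area grid is supplied; simple mean otherwise). Pearson's r
is computed from the raw-sums formula and cross-checked in the tests
against the covariance formulation and an independent library
implementation. Strength is classified on |r| — the conventional verbal
scale is printed for positive r but applied to negative coefficients in
practice — with half-open bins at 0.2/0.4/0.6/0.8 so no value falls
between bins; boundary values take the upper bin. Significance uses the
exact t transform `t = r·√((n−2)/(1−r²))` with n−2 degrees of freedom,
two-sided; |r| = 1 returns p = 0 as the degenerate limit. With the default
sampling design (2000–2020 every 5 years, n = 5) even r = 0.75 gives
p ≈ 0.14: the design has almost no power, which is why strong seasonal
correlations can still be reported as not statistically significant.

The packaged reference series (`data/tanzania_seasonal_means.csv`) are
published seasonal means for the January-April and June-September windows.
Only the June-September pair is internally consistent with its published
coefficients (0.75 rainfall–NDVI, −0.77 temperature–NDVI); the
January-April values printed alongside yield r ≈ 0.30 and −0.82, which
cannot be reconciled with the narrative values reported for that window,
so June-September is the reference pair for verification.

## Synthetic climate generator

The generator produces the *structure* the analysis assumes, not a
statistical emulation of any satellite product.

**Rainfall.** The month-of-year profile is a mixture of wrapped Gaussian
bumps (σ = 1.2 months): one centered on April for unimodal regimes, two
centered on April (weight 0.6) and November (weight 0.4) for bimodal —
long rains peaking within March–May, short rains within October–December.
Each cell-year draws an annual total inside the regime's range (defaults
750–1200 mm/yr bimodal, 300–2000 mm/yr unimodal) as a 50/50 convex blend
of a smooth spatial field and a per-year scalar, both rescaled to [0, 1]:
the blend guarantees totals stay inside the range at zero noise while
giving the domain mean a genuine wet-year/dry-year signal — without the
scalar term, rescaling the spatial field each year pins the domain mean
and the interannual correlations the analysis studies would have no
signal to recover. Noise is a multiplicative Gaussian factor truncated at
zero, keeping rainfall non-negative and dry months dry.

**Temperature.** A smooth base field with cell means inside the configured
range (default 20–30 °C), a mild seasonal cosine (amplitude 1.5 °C, warm
peak in February) kept inside the range by construction, additive noise,
and a small negative response to the concurrent rainfall anomaly
(−0.01 °C per mm by default). The coupling stands for cloud and
evaporative cooling; it is what makes wet years measurably cooler, giving
seasonal-mean temperature an interannual signal that opposes rainfall —
the pattern behind observed positive rain–NDVI and negative
temperature–NDVI correlations.

**NDVI.** `clip(base + g_r·rain + g_t·(T − T_ref) + noise, −1, 1)` with
g_r ≥ 0 (default 0.0015 per mm), g_t ≤ 0 (default −0.05 per °C), base 0.25
and T_ref the temperature-range midpoint (absorbing the reference level
into the base keeps the base itself a realistic NDVI). The rainfall term
can be lagged (`ndvi_lag_months`); the default is the concurrent month.
At monthly compositing the grass/crop greenness response time (two to
three weeks) falls within the composite month, and a cross-year lag would
couple January greenness to the previous year's independent December draw,
injecting a decoupling between seasonal NDVI and seasonal rainfall that
the generated world's vegetation is not supposed to have. Studies of
delayed response can set the lag explicitly.

**Land cover.** Water is one contiguous blob grown from a seeded origin to
exactly `round(water_fraction·n_cells)` cells (a lake, not salt-and-pepper
noise); a smooth-field threshold marks ~40 % of the remaining land as
cropland. Only the water count is contractual.

**Seeding.** One root seed is split per variable via `SeedSequence.spawn`;
equal (spec, seed) gives bit-identical cubes and masks.

### What the generator does not emulate

No orography, ITCZ dynamics, drought persistence across years, or spatial
autocorrelation beyond field smoothness; no attempt to match CHIRPS/MODIS
marginal distributions. Passing tests therefore demonstrate that the
*method* behaves correctly on data with the assumed seasonal and coupling
structure — they do not validate any country-level percentage obtained
from real satellite inputs, and the countrywide suitability percentages
reported from such inputs are treated here only as ordering properties
(wet-season windows outrank dry-season windows).

## Problem sizes and numerical choices

The bundled analysis and verification runs use a 30×30 grid over three
years for mapping/ranking and a 20×20 grid over 22 years (sampled every
5 years, n = 5) for the correlation experiments — small enough to run in
seconds, large enough that every masking, wrapping and ranking branch is
exercised. Degenerate inputs are handled explicitly: all-equal series in
min–max normalization (zeros + warning), constant series in Pearson r
(error), |r| = 1 in the p-value (0 with the degenerate-limit convention),
single-window ranking (z ≡ 0), and zero countable land area (error).

## Known limitations

Inputs must share one geometry; there is no resampling. Suitability is
binary, not graded ECOCROP membership. The growth cycle is represented by
the fixed window length, not by day-resolution phenology. Correlations
are domain-mean, not per-pixel, and the default n = 5 sampling has very
low statistical power by design of the emulated study.
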