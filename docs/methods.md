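# Methods

## Model structure and assumptions

`waterbal` is a single-bucket, daily, cell-independent water balance in the
Thornthwaite lineage. Each cell is closed: no lateral flow, no groundwater,
no routing — same-day surplus is runoff. The prognostic state is two storages,
snowpack SWE and soil water (both mm); everything else is a diagnostic flux.
The intra-day order of operations is fixed and documented, because it is part
of the model definition:

1. canopy interception (fraction of precipitation, evaporated the same day,
   counted inside reported AET);
2. rain/snow partition of the throughfall, snowfall added to the pack,
   *then* degree-day melt of the updated pack;
3. PET from temperature and solar geometry, multiplied by the terrain
   heat-load index;
4. NDVI scaling of the PET demand presented to the soil;
5. soil bucket update (supply-first, then the drying curve), runoff.

Daily mean temperature is `(tmin + tmax)/2` everywhere — the convention for
daily-minimum/maximum forcing products.

### Snow

The rain–snow partition is a clamped ramp in daily mean temperature: all snow
at/below `t50 − width`, half at `t50`, all rain at/above `t50 + width`. A
clamped, renormalised logistic with the same three anchor points is available
behind the same interface (`SnowParams.partition = "logistic"`); both satisfy
the same contract, and the cited regional partition coefficients can be
dropped in as a per-cell `t50` grid without any interface change. Melt is
temperature-index: `min(SWE, melt_factor · max(T − threshold, 0))`, with melt
computed after same-day snowfall joins the pack. Defaults: `t50` = 1.0 °C,
`width` = 3 °C, `melt_factor` = 4 mm °C⁻¹ day⁻¹, `threshold` = 0 °C —
standard temperature-index values. Sublimation is not modelled separately.

### PET

Oudin's temperature formulation: `PET = Rₐ/λ · (T + 5)/100` mm/day for
`T + 5 > 0`, else 0, with `λ` = 2.45 MJ kg⁻¹. `Rₐ` is the FAO-56
extraterrestrial radiation closed form (solar constant 0.0820 MJ m⁻² min⁻¹,
inverse relative distance `dr = 1 + 0.033·cos(2πJ/365)`, declination
`δ = 0.409·sin(2πJ/365 − 1.39)` recomputed every day, sunset hour angle
clamped so polar night yields exactly zero). Both `λ` and the 5 °C offset are
config keys for sensitivity testing.

Terrain is handled by a McCune–Keon-style heat-load index on aspect folded
about the southwest axis, `folded = |180 − |aspect − 225||`, normalised so a
flat cell is exactly 1. The index **multiplies the finished Oudin PET**. The
design was genuinely open (an equivalent-latitude transform is an
alternative); multiplying final PET keeps the −5 °C cutoff
terrain-independent and isolates the adjustment behind `daily_pet`. The
published heat-load fit covers 0–60° latitude; cells outside are clamped with
a warning, and southern-hemisphere cells are treated by absolute latitude.

### AET, CWD, soil

The NDVI climatology (365 daily values; Feb 29 maps to the Feb 28 entry)
scales the *demand* presented to the soil: `demand = PET · s(NDVI)` with
`s` linear from the lower bound at NDVI ≤ 0 to the upper bound at NDVI = 1
(defaults 0 and 1). Reported PET — and therefore CWD — is unscaled, which
keeps `CWD = PET − AET` literal. This is the single most consequential
interpretation in the model: scaling supply instead, or scaling reported PET,
would change CWD everywhere vegetation is sparse.

On supply days (`water_in ≥ demand`) demand is met exactly; the surplus
recharges the bucket to WHC and then runs off. On deficit days the bucket is
drawn down the Thornthwaite–Mather exponential curve,
`extraction = soil · (1 − e^(−unmet/WHC))`, which makes AET decline smoothly
as the soil dries and guarantees `0 ≤ soil ≤ WHC`, `0 ≤ AET ≤ PET` (without
interception), and `CWD ≥ 0` by construction. Interception loss is added to
reported AET (evaporation and transpiration are one stream in this model
class); its default of 0 makes the feature opt-in.

Mass closure — `Σprecip = ΣAET + Σrunoff + Δ(SWE + soil)` — holds to
~10⁻¹² mm/yr in double precision and is computed inside the engine from
float64 accumulators regardless of the storage dtype of the outputs, then
reported with every run.

## Simulation

Cells are independent, so the engine vectorises across cells and loops over
days; tiled ("chunked") execution is bit-identical to a whole-grid run and is
tested as such. Radiation is precomputed per unique day-of-year, and NDVI
scalars per climatology day. Default initial state is SWE = 0 and soil = WHC
at the run start; `spin_up` (cycling the first forcing year, reporting
max |Δstate| between the last two cycles) is the principled alternative.
First-year totals are burn-in sensitive either way. Nodata (NaN) forcing on a
cell-day makes all of that cell-day's outputs nodata; storages carry across
the gap unchanged.

Annual totals accumulate in float64, for calendar years or water years
(Oct 1 – Sep 30, labelled by the ending calendar year); incomplete years are
dropped with a warning. Snow-phenology metrics per complete water year:
first day with SWE > 0, last such day + 1, peak SWE, and the count of
snow-covered days; snow-free years carry a −1 sentinel for the day metrics.

Both the Gregorian and the 365-day no-leap calendar are supported; the
no-leap calendar is the native convention of Daymet-style forcing and of the
synthetic generator.

## Trend and change-vector analysis

Per-pixel trends are ordinary least squares of annual totals on calendar year
(uncentered; the slope is shift-invariant and the intercept is documented as
at year 0). Significance is deliberately not computed by default — the
intended use is broad spatial patterns of change, not inference — but a
p-value option exists. Pixels with fewer than 3 non-missing years get a
sentinel result. The normalized index is `(slope / period mean) · 10`, stored
as a fraction of the mean per decade; rendering as percent (×100) happens
only in reporting. Both the trend period and the normalisation period are
explicit parameters.

Change vectors: annual totals averaged over two periods (defaults 1980–1999
and 2000–2019) define two points in (CWD, AET) space with CWD on the
horizontal axis; intensity is the Euclidean distance between them and the
direction class is the quadrant of the displacement. Tie-break: a zero
displacement component counts as increasing; the zero vector is "no change".

Bivariate zones are marginal equal-count quantile bins (k × k for n_zones =
k²) with boundary values assigned to the lower bin — one defensible reading
of an "equal-area zones" construction; a true 2-D equal-area tiling would be
an alternative. Zone labels are invariant under monotone transforms of either
axis by construction. Point ("centroid") vectors use nearest-cell extraction
through the affine transform; out-of-bounds points are skipped with a warning
and a reported count.

## Synthetic data and what the tests do (and do not) show

The generator produces temperature as an annual sinusoid plus elevation lapse,
linear trend, and i.i.d. Gaussian daily noise, and precipitation as a
Bernoulli–gamma process with seasonal modulation of wet-day probability, an
optional multiplicative trend, and optional orographic enhancement. A
synthetic elevation ramp exists only inside the fixture layer — the model
itself never consumes elevation. Scenario conditions (fixed once, at design
time):

* `drying_west` — semi-arid (~245 mm/yr), warm, +0.6 °C/decade warming,
  −4 %/decade precipitation: water supply shrinks while demand grows, so CWD
  rises.
* `wetting_east` — humid (~790 mm/yr), +0.1 °C/decade, +6 %/decade
  precipitation: AET rises toward demand and CWD falls.
* `alpine_gradient` — a 500–4300 m ramp with a −5.0 °C/km lapse from a 17 °C
  base (so the ramp top sits near the snow/melt margin), warming amplified
  with elevation (+0.25 °C/decade per km on a 0.4 base) and orographic
  precipitation (+30 %/km): the largest bivariate change concentrates at high
  elevation, where snow-season shifts move both AET and CWD. In an earlier
  design with a colder, steeper lapse the ramp top was permanently frozen and
  absolute changes there vanished — the documented amplification is what
  makes the intended high-elevation mechanism operate.

What the synthetic fixtures deliberately do **not** emulate: spatial
correlation of weather, autocorrelated (storm-sequence) precipitation,
humidity/wind (excluded by the Oudin choice), vegetation dynamics (NDVI is a
fixed climatology), and observational error structure. Passing tests
therefore demonstrate numerical and structural correctness of the model and
analysis chain — conservation, identities, estimator behaviour, direction of
response to imposed trends — not fidelity to any real landscape.

Default problem sizes — 10×10 cells × 40 years for scenario analyses, with a
50×50 × 40-year run exercised for scaling — were chosen so the full test
suite and the acceptance script each run comfortably on a single CPU; the
engine itself is size-agnostic.

## Numerical choices and degenerate inputs

* Double-precision accumulation always; output storage dtype is a parameter
  (float32 for large grids).
* `rain + snowfall = precip` and the bucket budget close exactly by
  construction (the complement is computed by subtraction, not twice).
* Quantile bin edges use linear-interpolation quantiles; values exactly on an
  edge go to the lower bin.
* Division guards: normalized index is NaN where the mean is 0; trend
  sentinel (NaN + reason) below 3 points; snow metrics use −1 sentinels.
* Zero-length periods, misaligned grids, unknown config keys, missing
  variables, calendar gaps, and unit mismatches all raise named errors; units
  are mandatory metadata and are never guessed.

## Known limitations

* A single soil layer with no lateral transfer: cells over lakes, glaciers,
  or zero-WHC substrates are out of model scope.
* The rain–snow partition and NDVI→AET scaling are generic contracts with
  configurable parameters, not fitted regional coefficient sets; supplying
  fitted `t50` grids or scalar bounds is the intended calibration path.
* Oudin PET ignores humidity, wind, and observed radiation by design; it
  trades physical completeness for robustness when only temperature grids
  exist.
* GeoTIFF output carries the affine transform and nodata in standard tags but
  encodes the CRS as a JSON side field rather than a GeoKey directory, and
  supports north-up transforms only.
* NetCDF output is classic (NetCDF3) format.
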