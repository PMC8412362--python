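"""Synthetic forcing and attribute generators with known, recoverable structure.

Everything the model consumes can be generated here, so the whole pipeline is
testable without downloading any real data.  Temperature follows an annual
sinusoid with an elevation lapse, optional linear trend, and Gaussian daily
noise; precipitation is a Bernoulli–gamma process with seasonal modulation and
an optional multiplicative trend.  A synthetic "elevation" field exists only
inside this module — it drives lapse rates, orographic precipitation, and
attribute gradients, and is never consumed by the model itself.

Three named scenarios bundle conditions emulating the qualitative regimes the
analysis layer is meant to resolve: ``drying_west`` (warm, semi-arid, warming
with declining precipitation → rising CWD), ``wetting_east`` (humid, nearly
stationary temperature, rising precipitation → rising AET, falling CWD), and
``alpine_gradient`` (a 500–4300 m elevation ramp with elevation-amplified
warming and orographic precipitation → largest bivariate change at altitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._calendar import NOLEAP, DailyIndex
from .forcing_io import Affine, CellAttributes, GridStack
from .soil import ModelParams

__all__ = ["TemperatureModel", "PrecipModel", "AttributeModel", "FixtureSpec",
           "FixtureBundle", "SCENARIOS", "make_forcing", "make_attributes",
           "make_elevation", "make_scenario"]


@dataclass
class TemperatureModel:
    """Annual-sinusoid daily temperature (°C) with lapse, trend, and noise."""

    mean_c: float = 8.0                  # sea-level-ish annual mean at elevation 0 of the ramp
    amplitude_c: float = 11.0            # half peak-to-trough seasonal swing
    peak_doy: int = 200                  # warmest day of year
    lapse_c_per_km: float = -6.5
    trend_c_per_decade: float = 0.0
    trend_amplification_per_km: float = 0.0  # extra °C/decade per km of elevation
    noise_sd_c: float = 2.0              # i.i.d. daily noise
    diurnal_range_c: float = 10.0        # tmax - tmin


@dataclass
class PrecipModel:
    """Bernoulli–gamma daily precipitation (mm) with seasonality and trend."""

    wet_prob: float = 0.25
    gamma_shape: float = 0.7
    gamma_scale_mm: float = 6.0
    seasonal_amplitude: float = 0.3      # relative modulation of wet probability
    peak_doy: int = 60                   # wettest season centre (winter-wet default)
    trend_pct_per_decade: float = 0.0    # multiplicative trend on amounts
    orographic_per_km: float = 0.0       # relative amount increase per km elevation


@dataclass
class AttributeModel:
    """Static attribute fields: elevation ramp, terrain, soils, vegetation."""

    elevation_min_m: float = 500.0
    elevation_max_m: float = 1500.0      # ramp along the column axis (west -> east)
    slope_max_deg: float = 25.0
    whc_range_mm: tuple[float, float] = (50.0, 300.0)
    ndvi_summer: float = 0.7
    ndvi_winter: float = 0.2
    ndvi_peak_doy: int = 200
    latitude_range: tuple[float, float] = (38.0, 45.0)  # north (row 0) .. south
    snow_t50_c: float = 1.0


@dataclass
class FixtureSpec:
    """Full recipe for one synthetic dataset; a fixed seed gives byte-identical output."""

    shape: tuple[int, int] = (10, 10)
    years: int = 40
    start_year: int = 1980
    seed: int = 0
    calendar: str = NOLEAP
    temperature: TemperatureModel = field(default_factory=TemperatureModel)
    precip: PrecipModel = field(default_factory=PrecipModel)
    attributes: AttributeModel = field(default_factory=AttributeModel)
    transform: Affine = Affine.from_origin(-110.0, 45.0, 0.01, 0.01)
    crs: str = "EPSG:4326"


@dataclass
class FixtureBundle:
    """Everything a model run needs, plus the fixture-only elevation field."""

    forcing: dict[str, GridStack]
    attributes: CellAttributes
    elevation: np.ndarray
    params: ModelParams
    spec: FixtureSpec


def make_elevation(spec: FixtureSpec) -> np.ndarray:
    """Elevation (m) increasing linearly along the column axis."""
    nrow, ncol = spec.shape
    a = spec.attributes
    ramp = np.linspace(a.elevation_min_m, a.elevation_max_m, ncol)
    return np.broadcast_to(ramp, (nrow, ncol)).copy()


def make_attributes(spec: FixtureSpec) -> tuple[CellAttributes, np.ndarray]:
    """Generate static attributes; returns (CellAttributes, elevation grid).

    Terrain (slope/aspect) and WHC are seeded random fields; latitude varies
    linearly from north (row 0) to south; the NDVI climatology is a shared
    annual sinusoid between the winter and summer greenness levels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    nrow, ncol = spec.shape
    a = spec.attributes
    elevation = make_elevation(spec)
    lat = np.broadcast_to(
        np.linspace(a.latitude_range[1], a.latitude_range[0], nrow)[:, None],
        (nrow, ncol)).copy()
    slope = rng.uniform(0.0, a.slope_max_deg, size=spec.shape)
    aspect = rng.uniform(0.0, 360.0, size=spec.shape) % 360.0
    whc = rng.uniform(*a.whc_range_mm, size=spec.shape)
    doy = np.arange(1, 366)
    mid = 0.5 * (a.ndvi_summer + a.ndvi_winter)
    half = 0.5 * (a.ndvi_summer - a.ndvi_winter)
    ndvi = mid + half * np.cos(2.0 * np.pi * (doy - a.ndvi_peak_doy) / 365.0)
    attrs = CellAttributes(latitude=lat, slope=slope, aspect=aspect, whc=whc,
                           snow_t50=np.full(spec.shape, a.snow_t50_c),
                           ndvi_climatology=ndvi,
                           transform=spec.transform, crs=spec.crs)
    return attrs, elevation


def make_forcing(spec: FixtureSpec) -> dict[str, GridStack]:
    """Generate daily tmin/tmax/prcp GridStacks from the spec (reproducible)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    nrow, ncol = spec.shape
    n_cells = nrow * ncol
    if spec.calendar == NOLEAP:
        n_days = spec.years * 365
    else:
        import pandas as pd
        n_days = len(pd.date_range(f"{spec.start_year}-01-01",
                                   f"{spec.start_year + spec.years - 1}-12-31"))
    index = DailyIndex.date_range((spec.start_year, 1, 1), n_days, spec.calendar)
    doy = index.day_of_year
    decades = np.arange(n_days) / (10.0 * 365.25 if spec.calendar != NOLEAP else 3650.0)

    elev_km = (make_elevation(spec) / 1000.0).reshape(1, n_cells)
    tm = spec.temperature
    seasonal = tm.mean_c + tm.amplitude_c * np.cos(
        2.0 * np.pi * (doy - tm.peak_doy) / 365.0)
    trend = (tm.trend_c_per_decade
             + tm.trend_amplification_per_km * elev_km) * decades[:, None]
    tmean = (seasonal[:, None] + tm.lapse_c_per_km * elev_km + trend
             + rng.normal(0.0, tm.noise_sd_c, size=(n_days, n_cells)))
    tmin = tmean - tm.diurnal_range_c / 2.0
    tmax = tmean + tm.diurnal_range_c / 2.0

    pm = spec.precip
    p_wet = np.clip(pm.wet_prob * (1.0 + pm.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - pm.peak_doy) / 365.0)), 0.0, 1.0)
    wet = rng.random(size=(n_days, n_cells)) < p_wet[:, None]
    amounts = rng.gamma(pm.gamma_shape, pm.gamma_scale_mm, size=(n_days, n_cells))
    trend_factor = np.maximum(1.0 + pm.trend_pct_per_decade / 100.0 * decades, 0.0)
    oro = 1.0 + pm.orographic_per_km * elev_km
    prcp = wet * amounts * trend_factor[:, None] * oro

    def stack(name, data, units):
        return GridStack(name, data.reshape(n_days, nrow, ncol), index,
                         spec.transform, spec.crs, units=units)

    return {"tmin": stack("tmin", tmin, "degC"),
            "tmax": stack("tmax", tmax, "degC"),
            "prcp": stack("prcp", prcp, "mm")}


# ----------------------------------------------------------------------
# named scenarios (fixed study conditions; see docs/methods.md)

def _drying_west(seed: int) -> FixtureSpec:
    return FixtureSpec(
        seed=seed,
        temperature=TemperatureModel(mean_c=13.0, amplitude_c=11.0,
                                     trend_c_per_decade=0.6, noise_sd_c=2.0),
        precip=PrecipModel(wet_prob=0.12, gamma_shape=0.7, gamma_scale_mm=8.0,
                           seasonal_amplitude=0.3, peak_doy=60,
                           trend_pct_per_decade=-4.0),
        attributes=AttributeModel(elevation_min_m=800.0, elevation_max_m=1600.0,
                                  whc_range_mm=(50.0, 200.0),
                                  ndvi_summer=0.5, ndvi_winter=0.2,
                                  latitude_range=(36.0, 42.0)))


def _wetting_east(seed: int) -> FixtureSpec:
    return FixtureSpec(
        seed=seed,
        temperature=TemperatureModel(mean_c=12.0, amplitude_c=10.0,
                                     trend_c_per_decade=0.1, noise_sd_c=2.0),
        precip=PrecipModel(wet_prob=0.30, gamma_shape=0.8, gamma_scale_mm=9.0,
                           seasonal_amplitude=0.2, peak_doy=180,
                           trend_pct_per_decade=6.0),
        attributes=AttributeModel(elevation_min_m=100.0, elevation_max_m=600.0,
                                  whc_range_mm=(100.0, 300.0),
                                  ndvi_summer=0.8, ndvi_winter=0.3,
                                  latitude_range=(34.0, 42.0)))


def _alpine_gradient(seed: int) -> FixtureSpec:
    return FixtureSpec(
        seed=seed,
        temperature=TemperatureModel(mean_c=17.0, amplitude_c=10.0,
                                     lapse_c_per_km=-5.0,
                                     trend_c_per_decade=0.4,
                                     trend_amplification_per_km=0.25,
                                     noise_sd_c=2.0),
        precip=PrecipModel(wet_prob=0.25, gamma_shape=0.7, gamma_scale_mm=6.0,
                           seasonal_amplitude=0.4, peak_doy=30,
                           orographic_per_km=0.3),
        attributes=AttributeModel(elevation_min_m=500.0, elevation_max_m=4300.0,
                                  whc_range_mm=(50.0, 250.0),
                                  ndvi_summer=0.6, ndvi_winter=0.2,
                                  latitude_range=(36.0, 37.5)))


SCENARIOS = {
    "drying_west": _drying_west,
    "wetting_east": _wetting_east,
    "alpine_gradient": _alpine_gradient,
}


def make_scenario(name: str, seed: int = 0, *, shape: tuple[int, int] | None = None,
                  years: int | None = None) -> FixtureBundle:
    """Build the full input bundle for a named scenario.

    ``shape``/``years`` override the default 10×10 grid and 40-year span
    (1980–2019) without touching the climate conditions themselves.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    spec = SCENARIOS[name](seed)
    if shape is not None:
        spec = replace(spec, shape=tuple(shape))
    if years is not None:
        spec = replace(spec, years=int(years))
    attrs, elevation = make_attributes(spec)
    forcing = make_forcing(spec)
    return FixtureBundle(forcing, attrs, elevation, ModelParams(), spec)
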