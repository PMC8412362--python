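"""Daily grid orchestration: full runs, spin-up, annual totals, snow phenology.

Cells are independent (no lateral coupling), so the engine vectorises each day
across all cells and loops over days; chunked (tiled) execution gives
bit-identical results to an unchunked run.  Flux accumulation for the
mass-balance report is always double precision, whatever the storage dtype of
the output stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._calendar import DailyIndex
from .forcing_io import CellAttributes, ForcingSeries, GridAlignmentError, GridStack
from .pet import extraterrestrial_radiation, heat_load_index, oudin_pet
from .soil import FLUX_NAMES, ModelParams, WaterState, ndvi_aet_scalar, step_water

__all__ = ["RunResult", "AnnualSeries", "SnowMetrics", "run", "run_site",
           "spin_up", "annual_totals", "snow_phenology"]

_OUTPUT_UNITS = {name: "mm" for name in FLUX_NAMES}

#: sentinel for snow-phenology day metrics in snow-free water years
NO_SNOW_SENTINEL = -1


@dataclass
class RunResult:
    """Daily output stacks plus the run's double-precision mass-balance report.

    ``mass_balance`` holds per-cell grids: total precip, aet, runoff, the
    storage change (SWE + soil), the closure residual, and the residual per
    simulated year.
    """

    outputs: dict[str, GridStack]
    mass_balance: dict[str, np.ndarray]
    final_state: WaterState
    n_years: float


@dataclass
class AnnualSeries:
    """Annual (calendar or water-year) totals per variable per cell."""

    years: np.ndarray
    data: dict[str, np.ndarray]  # var -> (n_years, nrow, ncol)
    kind: str = "calendar"       # or "water_year"

    def mean(self, start: int | None = None, end: int | None = None) -> dict[str, np.ndarray]:
        """Per-cell mean annual total over [start, end] inclusive."""
        sel = np.ones(len(self.years), dtype=bool)
        if start is not None:
            sel &= self.years >= start
        if end is not None:
            sel &= self.years <= end
        if not sel.any():
            raise ValueError(f"no years in range [{start}, {end}] "
                             f"(available {self.years.min()}..{self.years.max()})")
        return {k: v[sel].mean(axis=0) for k, v in self.data.items()}


@dataclass
class SnowMetrics:
    """Water-year snow-cover metrics (snow cover means SWE > 0).

    Day metrics are 1-based days of the water year; snow-free years carry the
    sentinel ``NO_SNOW_SENTINEL`` for first/last and 0 for peak/count.
    """

    water_years: np.ndarray
    first_snow_day: np.ndarray      # (n_wy, nrow, ncol) int
    last_snow_day_plus1: np.ndarray
    peak_swe: np.ndarray            # mm
    snow_days: np.ndarray           # count of days with SWE > 0


# ----------------------------------------------------------------------
# core engine

def _flatten_attributes(attrs: CellAttributes, shape):
    nrow, ncol = shape
    n = nrow * ncol

    def flat(v):
        return np.broadcast_to(np.asarray(v, dtype=float), shape).reshape(n)

    ndvi = attrs.ndvi_climatology
    if ndvi.ndim == 1:
        ndvi = np.broadcast_to(ndvi[:, None, None], (365, nrow, ncol))
    ndvi_flat = ndvi.reshape(365, n)
    t50 = None if attrs.snow_t50 is None else flat(attrs.snow_t50)
    return (flat(attrs.latitude), flat(attrs.slope), flat(attrs.aspect),
            flat(attrs.whc), t50, ndvi_flat)


def _simulate_block(tmin, tmax, precip, index: DailyIndex, lat, slope, aspect,
                    whc, t50, ndvi, params: ModelParams, state: WaterState,
                    dtype, keep):
    """Run the daily loop on flattened (T, N) forcing; returns per-variable
    (T, N) arrays in ``dtype`` plus float64 mass accumulators."""
    from .soil import SoilParams

    T, N = precip.shape
    doy = index.day_of_year
    clim_idx = index.climatology_index
    hl = heat_load_index(lat, slope, aspect)
    scal = ndvi_aet_scalar(ndvi, params.soil.aet_scalar_bounds)  # (365, N)

    # Ra depends only on (latitude, day of year): precompute rows per unique doy.
    udoy, doy_inv = np.unique(doy, return_inverse=True)
    ra_tab = np.empty((len(udoy), N))
    for i, j in enumerate(udoy):
        ra_tab[i] = extraterrestrial_radiation(lat, int(j))

    soil_params = SoilParams(whc, params.soil.interception_fraction,
                             params.soil.aet_scalar_bounds)
    block_params = ModelParams(params.snow, soil_params, params.pet)

    out = {name: np.empty((T, N), dtype=dtype) for name in keep}
    sum_p = np.zeros(N)
    sum_aet = np.zeros(N)
    sum_runoff = np.zeros(N)
    state = WaterState(np.broadcast_to(np.asarray(state.swe, float), (N,)).copy(),
                       np.broadcast_to(np.asarray(state.soil, float), (N,)).copy())

    for t in range(T):
        tmean = (tmin[t] + tmax[t]) / 2.0
        p = precip[t]
        valid = np.isfinite(tmean) & np.isfinite(p)
        pet = oudin_pet(ra_tab[doy_inv[t]], tmean, params.pet) * hl
        prev_swe, prev_soil = state.swe, state.soil
        state, fx = step_water(state, tmean, p, pet, scal[clim_idx[t]],
                               block_params, snow_t50=t50)
        if not valid.all():
            # nodata forcing: outputs are nodata, storages carry over unchanged
            state = WaterState(np.where(valid, state.swe, prev_swe),
                               np.where(valid, state.soil, prev_soil))
            fx.soil_water = state.soil
            fx.swe = state.swe
        for name in keep:
            v = getattr(fx, name)
            out[name][t] = np.where(valid, v, np.nan) if not valid.all() else v
        sum_p += np.where(valid, p, 0.0)
        sum_aet += np.where(valid, fx.aet, 0.0)
        sum_runoff += np.where(valid, fx.runoff, 0.0)

    return out, state, sum_p, sum_aet, sum_runoff


def _check_alignment(forcing: dict[str, GridStack]):
    required = ("tmin", "tmax", "prcp")
    missing = [k for k in required if k not in forcing]
    if missing:
        raise KeyError(f"forcing is missing variables {missing}")
    shapes = {k: v.data.shape for k, v in forcing.items()}
    if len(set(shapes.values())) != 1:
        raise GridAlignmentError(f"forcing grids are misaligned: {shapes}")
    ref = forcing["tmin"].index
    for k in ("tmax", "prcp"):
        if not forcing[k].index.equals(ref):
            raise GridAlignmentError(f"time axis of {k!r} differs from tmin")


def _iter_tiles(nrow, ncol, chunks):
    if chunks is None:
        yield slice(0, nrow), slice(0, ncol)
        return
    ch_r, ch_c = chunks
    for r0 in range(0, nrow, ch_r):
        for c0 in range(0, ncol, ch_c):
            yield slice(r0, min(r0 + ch_r, nrow)), slice(c0, min(c0 + ch_c, ncol))


def run(forcing: dict[str, GridStack], attributes: CellAttributes,
        params: ModelParams | None = None, initial: WaterState | None = None, *,
        chunks: tuple[int, int] | None = None, dtype=np.float64,
        variables: tuple[str, ...] | None = None) -> RunResult:
    """Run the daily water balance over a grid.

    Parameters
    ----------
    forcing
        ``{"tmin", "tmax", "prcp"}`` GridStacks on one shared grid and time axis.
    attributes
        Static cell attributes; WHC and (optionally) the snow partition
        midpoint come from here.
    initial
        Starting storages; default SWE = 0 and soil = WHC (use
        :func:`spin_up` for a principled alternative).
    chunks
        ``(rows, cols)`` tile size.  Results are bit-identical for any
        chunking because cells are independent.
    dtype
        Storage dtype of the output stacks (accumulation is always float64).
    variables
        Subset of output variables to materialise (default: all).

    Returns
    -------
    RunResult with one GridStack per output variable, the per-cell float64
    mass-balance report, and the final state.
    """
    if params is None:
        params = ModelParams()
    _check_alignment(forcing)
    ref = forcing["tmin"]
    T, nrow, ncol = ref.data.shape
    attr_shape = attributes.grid_shape
    if attr_shape and attr_shape != (nrow, ncol):
        raise GridAlignmentError(
            f"attribute grid shape {attr_shape} != forcing grid shape {(nrow, ncol)}")
    keep = tuple(variables) if variables is not None else FLUX_NAMES
    unknown = set(keep) - set(FLUX_NAMES)
    if unknown:
        raise ValueError(f"unknown output variables {sorted(unknown)}")

    lat_f, slope_f, aspect_f, whc_f, t50_f, ndvi_f = _flatten_attributes(
        attributes, (nrow, ncol))
    if initial is None:
        init_flat = WaterState(swe=np.zeros(nrow * ncol), soil=whc_f.copy())
    else:
        init_flat = WaterState(
            np.broadcast_to(np.asarray(initial.swe, float), (nrow, ncol)).reshape(-1),
            np.broadcast_to(np.asarray(initial.soil, float), (nrow, ncol)).reshape(-1))

    out_full = {name: np.empty((T, nrow, ncol), dtype=dtype) for name in keep}
    sum_p = np.empty((nrow, ncol))
    sum_aet = np.empty((nrow, ncol))
    sum_runoff = np.empty((nrow, ncol))
    final_swe = np.empty((nrow, ncol))
    final_soil = np.empty((nrow, ncol))
    init_total = init_flat.total().reshape(nrow, ncol)

    cols = np.arange(nrow * ncol).reshape(nrow, ncol)
    for rs, cs in _iter_tiles(nrow, ncol, chunks):
        sel = cols[rs, cs].ravel()
        tile_shape = (rs.stop - rs.start, cs.stop - cs.start)
        block, state, bp, baet, brun = _simulate_block(
            forcing["tmin"].data[:, rs, cs].reshape(T, -1).astype(float, copy=False),
            forcing["tmax"].data[:, rs, cs].reshape(T, -1).astype(float, copy=False),
            forcing["prcp"].data[:, rs, cs].reshape(T, -1).astype(float, copy=False),
            ref.index, lat_f[sel], slope_f[sel], aspect_f[sel], whc_f[sel],
            None if t50_f is None else t50_f[sel], ndvi_f[:, sel],
            params, WaterState(init_flat.swe[sel], init_flat.soil[sel]),
            dtype, keep)
        for name in keep:
            out_full[name][:, rs, cs] = block[name].reshape(T, *tile_shape)
        sum_p[rs, cs] = bp.reshape(tile_shape)
        sum_aet[rs, cs] = baet.reshape(tile_shape)
        sum_runoff[rs, cs] = brun.reshape(tile_shape)
        final_swe[rs, cs] = state.swe.reshape(tile_shape)
        final_soil[rs, cs] = state.soil.reshape(tile_shape)

    n_years = T / ref.index.days_in_year(int(ref.index.years[0]))
    storage_change = (final_swe + final_soil) - init_total
    residual = sum_p - (sum_aet + sum_runoff + storage_change)
    mass_balance = {
        "precip": sum_p, "aet": sum_aet, "runoff": sum_runoff,
        "storage_change": storage_change, "residual": residual,
        "residual_per_year": residual / n_years,
    }
    outputs = {
        name: GridStack(name, out_full[name], ref.index, ref.transform, ref.crs,
                        units=_OUTPUT_UNITS[name])
        for name in keep}
    return RunResult(outputs, mass_balance,
                     WaterState(final_swe, final_soil), n_years)


def run_site(forcing: ForcingSeries, cell: CellAttributes,
             params: ModelParams | None = None,
             initial: WaterState | None = None) -> tuple[pd.DataFrame, dict]:
    """Run a single-site series; returns (daily DataFrame, mass-balance dict)."""
    if params is None:
        params = ModelParams()
    n = len(forcing)
    idx = forcing.index
    stacks = {
        "tmin": GridStack("tmin", forcing.tmin.reshape(n, 1, 1), idx, units="degC"),
        "tmax": GridStack("tmax", forcing.tmax.reshape(n, 1, 1), idx, units="degC"),
        "prcp": GridStack("prcp", forcing.precip.reshape(n, 1, 1), idx, units="mm"),
    }
    res = run(stacks, cell, params, initial)
    df = pd.DataFrame({name: res.outputs[name].data[:, 0, 0] for name in FLUX_NAMES})
    df.insert(0, "date", idx.isoformat())
    mb = {k: float(v[0, 0]) for k, v in res.mass_balance.items()}
    return df, mb


def spin_up(forcing: dict[str, GridStack], attributes: CellAttributes,
            params: ModelParams | None = None, n_cycles: int = 3
            ) -> tuple[WaterState, float]:
    """Cycle the first forcing year ``n_cycles`` times to initialise storages.

    Returns the end state and the convergence measure: max |Δstate| (mm)
    between the final two cycles (0.0 when ``n_cycles == 1``).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    _check_alignment(forcing)
    ref = forcing["tmin"]
    n_first = min(ref.index.days_in_year(int(ref.index.years[0])), len(ref.index))
    year = {k: GridStack(v.name, v.data[:n_first], v.index[:n_first],
                         v.transform, v.crs, units=v.units)
            for k, v in forcing.items()}
    state = None
    conv = np.inf
    for _ in range(n_cycles):
        prev = state
        res = run(year, attributes, params, initial=state,
                  variables=("swe", "soil_water"))
        state = res.final_state
        if prev is not None:
            conv = float(max(np.nanmax(np.abs(state.swe - prev.swe)),
                             np.nanmax(np.abs(state.soil - prev.soil))))
    return state, (conv if n_cycles > 1 else 0.0)


# ----------------------------------------------------------------------
# aggregation

def _year_labels(index: DailyIndex, water_year: bool):
    if water_year:
        labels, _ = index.water_year()
        expected = {int(y): index.days_in_water_year(int(y)) for y in np.unique(labels)}
    else:
        labels = index.years
        expected = {int(y): index.days_in_year(int(y)) for y in np.unique(labels)}
    return labels, expected


def annual_totals(stacks, water_year: bool = False) -> AnnualSeries:
    """Sum daily stacks to annual (calendar-year or water-year) totals per cell.

    Incomplete years at either end are dropped with a warning; float64
    accumulation regardless of storage dtype.
    """
    if isinstance(stacks, GridStack):
        stacks = {stacks.name: stacks}
    if not stacks:
        raise ValueError("no stacks given")
    ref = next(iter(stacks.values()))
    labels, expected = _year_labels(ref.index, water_year)
    uyears, counts = np.unique(labels, return_counts=True)
    complete = np.array([counts[i] == expected[int(y)] for i, y in enumerate(uyears)])
    if not complete.any():
        raise ValueError("no complete years in the daily index")
    if not complete.all():
        dropped = [int(y) for y in uyears[~complete]]
        warnings.warn(f"dropping incomplete year(s) {dropped}", stacklevel=2)
    kept_years = uyears[complete]

    data = {}
    for name, stack in stacks.items():
        if not stack.index.equals(ref.index):
            raise GridAlignmentError(f"stack {name!r} has a different time axis")
        totals = np.empty((len(kept_years),) + stack.data.shape[1:])
        for i, y in enumerate(kept_years):
            totals[i] = stack.data[labels == y].astype(np.float64).sum(axis=0)
        data[name] = totals
    return AnnualSeries(kept_years, data,
                        "water_year" if water_year else "calendar")


def snow_phenology(swe: GridStack) -> SnowMetrics:
    """Water-year snow metrics from a daily SWE stack.

    For each complete water year and cell: first day of the water year with
    SWE > 0, last such day + 1, peak SWE, and the count of days with SWE > 0.
    """
    index = swe.index
    labels, dowy = index.water_year()
    uyears, counts = np.unique(labels, return_counts=True)
    complete = np.array([counts[i] == index.days_in_water_year(int(y))
                         for i, y in enumerate(uyears)])
    if not complete.all():
        dropped = [int(y) for y in uyears[~complete]]
        warnings.warn(f"dropping incomplete water year(s) {dropped}", stacklevel=2)
    kept = uyears[complete]
    if len(kept) == 0:
        raise ValueError("no complete water years in the daily index")

    _, nrow, ncol = swe.data.shape
    nwy = len(kept)
    first = np.full((nwy, nrow, ncol), NO_SNOW_SENTINEL, dtype=np.int64)
    last_p1 = np.full((nwy, nrow, ncol), NO_SNOW_SENTINEL, dtype=np.int64)
    peak = np.zeros((nwy, nrow, ncol))
    days = np.zeros((nwy, nrow, ncol), dtype=np.int64)

    for i, y in enumerate(kept):
        sel = labels == y
        block = swe.data[sel].astype(np.float64)
        covered = block > 0
        any_snow = covered.any(axis=0)
        days[i] = covered.sum(axis=0)
        peak[i] = block.max(axis=0)
        first_idx = covered.argmax(axis=0)          # 0-based day of water year
        last_idx = block.shape[0] - 1 - covered[::-1].argmax(axis=0)
        first[i] = np.where(any_snow, first_idx + 1, NO_SNOW_SENTINEL)
        last_p1[i] = np.where(any_snow, last_idx + 2, NO_SNOW_SENTINEL)
    return SnowMetrics(kept, first, last_p1, peak, days)
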