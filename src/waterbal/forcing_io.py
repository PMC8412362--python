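"""Containers and I/O for daily forcing, static attributes, and model output grids.

Conventions enforced here and relied on everywhere else in the package:

* temperatures are °C, water depths and fluxes are mm — units are mandatory
  metadata, never guessed;
* the daily time axis is gap-free and strictly increasing, on either the
  Gregorian ("standard") or the Daymet-style 365-day ("noleap") calendar;
* row 0 is the northernmost row and the affine transform is the single source
  of georeferencing truth;
* missing data is NaN (the explicit nodata sentinel for float payloads).

Grids travel as NetCDF (classic format, CF-style attributes, written through
xarray's scipy backend) or GeoTIFF (via tifffile; north-up transforms only).
Site time series travel as CSV with ``date,tmin,tmax,prcp`` columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import NOLEAP, STANDARD, CalendarGapError, DailyIndex

__all__ = [
    "Affine", "GridStack", "ForcingSeries", "CellAttributes",
    "MissingVariableError", "UnitError", "GridAlignmentError", "CalendarGapError",
    "read_forcing", "write_outputs", "read_grid", "read_attributes",
    "write_attributes", "water_year_index",
]

#: canonical forcing variable names -> accepted unit spellings
_TEMP_UNITS = {"degc", "deg c", "c", "celsius", "degrees c", "degree_celsius", "°c"}
_DEPTH_UNITS = {"mm", "mm/day", "mm day-1", "kg m-2", "kg/m2", "kg m-2 day-1"}
_EXPECTED_UNITS = {"tmin": _TEMP_UNITS, "tmax": _TEMP_UNITS, "prcp": _DEPTH_UNITS}

_OUTPUT_LONG_NAMES = {
    "swe": "snow water equivalent",
    "pet": "potential evapotranspiration",
    "aet": "actual evapotranspiration",
    "cwd": "climatic water deficit",
    "soil_water": "soil water content",
    "runoff": "runoff",
    "rain": "rainfall",
    "snowfall": "snowfall water equivalent",
    "melt": "snowmelt",
    "interception_loss": "canopy interception loss",
    "tmin": "daily minimum temperature",
    "tmax": "daily maximum temperature",
    "prcp": "daily precipitation",
}


class MissingVariableError(KeyError):
    """A requested variable is absent from the file."""


class UnitError(ValueError):
    """Units missing or inconsistent with the model's °C / mm conventions."""


class GridAlignmentError(ValueError):
    """Grids that must share shape/transform do not."""


class Affine(NamedTuple):
    """Affine map from (col, row) pixel indices to world coordinates.

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f`` with (c, f) the
    coordinates of the outer corner of the top-left pixel (GDAL convention,
    row 0 at the north edge so ``e`` is negative for north-up grids).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def xy(self, row, col):
        """World coordinates of pixel centers."""
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def rowcol(self, x, y):
        """Pixel indices containing world points (floor convention)."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("degenerate affine transform")
        dx = np.asarray(x, dtype=float) - self.c
        dy = np.asarray(y, dtype=float) - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return np.floor(row).astype(np.int64), np.floor(col).astype(np.int64)


@dataclass
class GridStack:
    """A named daily 3-D (time × row × col) variable with georeferencing."""

    name: str
    data: np.ndarray
    index: DailyIndex
    transform: Affine = Affine.from_origin(0.0, 0.0, 1.0, 1.0)
    crs: str = ""
    units: str = ""
    nodata: float = float("nan")
    long_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"GridStack data must be 3-D (time,row,col); got {self.data.shape}")
        if len(self.index) != self.data.shape[0]:
            raise ValueError(
                f"time axis length {len(self.index)} != data.shape[0] {self.data.shape[0]}")
        self.index.validate_contiguous()
        if not self.long_name:
            self.long_name = _OUTPUT_LONG_NAMES.get(self.name, self.name)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ForcingSeries:
    """Daily tmin/tmax/precip for one site; the single-cell model driver."""

    index: DailyIndex
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        n = len(self.index)
        if not (len(self.tmin) == len(self.tmax) == len(self.precip) == n):
            raise ValueError("tmin/tmax/precip must match the daily index length")
        self.index.validate_contiguous()
        if np.any(self.precip[np.isfinite(self.precip)] < 0):
            raise ValueError("precipitation must be non-negative")
        both = np.isfinite(self.tmin) & np.isfinite(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise ValueError("tmax < tmin encountered")

    def __len__(self):
        return len(self.index)


@dataclass
class CellAttributes:
    """Static per-cell attributes; fields are scalars (site) or 2-D arrays (grid).

    ``snow_t50`` may be None, in which case the global snow-parameter default is
    used.  ``ndvi_climatology`` has leading length 365 (day-of-year, no-leap
    indexing; Feb 29 maps to the Feb 28 entry).
    """

    latitude: np.ndarray | float
    slope: np.ndarray | float = 0.0
    aspect: np.ndarray | float = 0.0
    whc: np.ndarray | float = 150.0
    snow_t50: np.ndarray | float | None = None
    ndvi_climatology: np.ndarray = field(default_factory=lambda: np.ones(365))
    transform: Affine = Affine.from_origin(0.0, 0.0, 1.0, 1.0)
    crs: str = ""

    def __post_init__(self):
        lat = np.asarray(self.latitude, dtype=float)
        if np.any(lat < -90) or np.any(lat > 90):
            raise ValueError("latitude outside [-90, 90]")
        slope = np.asarray(self.slope, dtype=float)
        if np.any(slope < 0) or np.any(slope > 90):
            raise ValueError("slope outside [0, 90] degrees")
        aspect = np.asarray(self.aspect, dtype=float)
        if np.any(aspect < 0) or np.any(aspect >= 360):
            raise ValueError("aspect outside [0, 360) degrees")
        if np.any(np.asarray(self.whc, dtype=float) <= 0):
            raise ValueError("whc must be > 0 mm")
        ndvi = np.asarray(self.ndvi_climatology, dtype=float)
        if ndvi.shape[0] != 365:
            raise ValueError("ndvi_climatology must have leading length 365")
        if np.nanmin(ndvi) < -1 or np.nanmax(ndvi) > 1:
            raise ValueError("NDVI outside [-1, 1]")
        self.ndvi_climatology = ndvi

    @property
    def grid_shape(self):
        lat = np.asarray(self.latitude)
        return lat.shape if lat.ndim == 2 else ()


def water_year_index(dates: DailyIndex) -> tuple[np.ndarray, np.ndarray]:
    """Map each day to (water-year label, day of water year).

    Water years run Oct 1 – Sep 30 and take the label of the ending calendar
    year; Oct 1 is day 1.
    """
    return dates.water_year()


# ----------------------------------------------------------------------
# units

def _check_units(canonical: str, declared: str | None, conversions: dict | None):
    """Return a multiplicative factor coercing ``declared`` units to °C/mm.

    Additive temperature conversions are not supported; anything not in the
    accepted spellings must come with an explicit factor in ``conversions``.
    """
    expected = _EXPECTED_UNITS.get(canonical, _DEPTH_UNITS)
    if declared is None or declared == "":
        raise UnitError(f"variable {canonical!r} has no units attribute; "
                        "units are mandatory metadata")
    if declared.strip().lower() in expected:
        return 1.0
    if conversions and canonical in conversions:
        return float(conversions[canonical])
    raise UnitError(
        f"variable {canonical!r} has units {declared!r}, expected one of "
        f"{sorted(expected)}; pass an explicit factor via unit_conversions to convert")


# ----------------------------------------------------------------------
# CSV (site) I/O

def _read_csv_forcing(path: Path) -> ForcingSeries:
    df = pd.read_csv(path)
    required = {"date", "tmin", "tmax", "prcp"}
    missing = required - set(df.columns)
    if missing:
        raise MissingVariableError(
            f"CSV {path} is missing required columns: {sorted(missing)}")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    idx = DailyIndex.from_pandas(dates)
    idx.validate_contiguous()
    return ForcingSeries(idx, df["tmin"].to_numpy(float),
                         df["tmax"].to_numpy(float), df["prcp"].to_numpy(float))


def write_site_csv(series: ForcingSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"date": series.index.isoformat(), "tmin": series.tmin,
                  "tmax": series.tmax, "prcp": series.precip}).to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
# NetCDF I/O (classic format via xarray's scipy backend)

def _y_x_coords(transform: Affine, nrow: int, ncol: int):
    x, _ = transform.xy(np.zeros(ncol), np.arange(ncol))
    _, y = transform.xy(np.arange(nrow), np.zeros(nrow))
    return y, x


def _stack_to_dataarray(stack: GridStack) -> xr.DataArray:
    nrow, ncol = stack.data.shape[1:]
    y, x = _y_x_coords(stack.transform, nrow, ncol)
    time = np.arange(len(stack.index), dtype=np.int32)
    da = xr.DataArray(
        stack.data, dims=("time", "y", "x"),
        coords={"time": ("time", time,
                         {"units": f"days since {stack.index.first_date}",
                          "calendar": stack.index.calendar}),
                "y": y, "x": x},
        name=stack.name,
        attrs={"units": stack.units, "long_name": stack.long_name,
               "nodata": float(stack.nodata)})
    return da


def _write_netcdf(stacks: list[GridStack], path: Path) -> Path:
    ds = xr.Dataset({s.name: _stack_to_dataarray(s) for s in stacks})
    t = stacks[0].transform
    ds.attrs["transform"] = [float(v) for v in t]
    ds.attrs["crs"] = stacks[0].crs
    ds.attrs["Conventions"] = "CF-1.8"
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")
    return path


def _index_from_time(var) -> DailyIndex:
    units = var.attrs.get("units", "")
    if not units.startswith("days since "):
        raise CalendarGapError(f"unsupported time units {units!r}")
    start = units[len("days since "):].strip()
    calendar = var.attrs.get("calendar", STANDARD)
    if calendar in ("365_day", "noleap"):
        calendar = NOLEAP
    elif calendar in ("standard", "gregorian", "proleptic_gregorian"):
        calendar = STANDARD
    offsets = np.asarray(var.values)
    if not np.array_equal(offsets, np.round(offsets)):
        raise CalendarGapError("time offsets are not whole days")
    offsets = offsets.astype(np.int64)
    diffs = np.diff(offsets)
    full = DailyIndex.date_range(start, int(offsets[-1]) + 1 if len(offsets) else 0, calendar)
    if np.any(diffs != 1):
        i = int(np.argmax(diffs != 1))
        missing = full.isoformat()[offsets[i] + 1]
        raise CalendarGapError(f"daily index has a gap: missing {missing}")
    if offsets[0] != 0:
        start_idx = DailyIndex.date_range(start, offsets[0] + 1, calendar)[-1:]
        return DailyIndex.date_range(
            (int(start_idx.years[0]), int(start_idx.months[0]), int(start_idx.days[0])),
            len(offsets), calendar)
    return full[:len(offsets)]


def _read_netcdf(path: Path, variables: dict[str, str] | None,
                 unit_conversions: dict | None):
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds.load()
    transform = Affine(*ds.attrs.get("transform", (1, 0, 0, 0, -1, 0)))
    crs = str(ds.attrs.get("crs", ""))
    if variables is None:
        variables = {name: name for name in ds.data_vars}
    out = {}
    for canonical, in_file in variables.items():
        if in_file not in ds.data_vars:
            raise MissingVariableError(
                f"variable {in_file!r} (for {canonical!r}) not found in {path}; "
                f"file has {sorted(ds.data_vars)}")
        var = ds[in_file]
        idx = _index_from_time(ds["time"])
        factor = 1.0
        if canonical in _EXPECTED_UNITS:
            factor = _check_units(canonical, var.attrs.get("units"), unit_conversions)
        data = var.values
        if factor != 1.0:
            data = data * factor
        out[canonical] = GridStack(
            canonical, data, idx, transform, crs,
            units=("degC" if canonical in ("tmin", "tmax") else
                   var.attrs.get("units", "")),
            nodata=float(var.attrs.get("nodata", np.nan)))
    return out


# ----------------------------------------------------------------------
# GeoTIFF I/O (tifffile; north-up transforms only)

def _write_geotiff(stack: GridStack, path: Path) -> Path:
    import tifffile

    if stack.transform.b != 0 or stack.transform.d != 0:
        raise ValueError("GeoTIFF output supports only north-up (unrotated) transforms")
    t = stack.transform
    desc = json.dumps({
        "name": stack.name, "units": stack.units, "crs": stack.crs,
        "start": stack.index.first_date, "calendar": stack.index.calendar,
        "n_days": len(stack.index), "nodata": float(stack.nodata)})
    extratags = [
        (33550, "d", 3, (abs(t.a), abs(t.e), 0.0)),          # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),     # ModelTiepoint
        (42113, "s", 0, str(stack.nodata)),                   # GDAL_NODATA
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, description=desc, extratags=extratags,
                     photometric="minisblack", metadata=None)
    return path


def _read_geotiff(path: Path) -> GridStack:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
        scale = page.tags.get(33550)
        tie = page.tags.get(33922)
        if scale is not None and tie is not None:
            sx, sy = scale.value[0], scale.value[1]
            west, north = tie.value[3], tie.value[4]
            transform = Affine.from_origin(west, north, sx, sy)
        else:
            transform = Affine.from_origin(0, 0, 1, 1)
    if data.ndim == 2:
        data = data[None]
    idx = DailyIndex.date_range(meta.get("start", "2000-01-01"), data.shape[0],
                                meta.get("calendar", STANDARD))
    return GridStack(meta.get("name", Path(path).stem), data, idx, transform,
                     meta.get("crs", ""), units=meta.get("units", ""),
                     nodata=float(meta.get("nodata", np.nan)))


# ----------------------------------------------------------------------
# public entry points

def read_forcing(path, variables: dict[str, str] | None = None, *,
                 unit_conversions: dict | None = None):
    """Read daily forcing from CSV (site) or NetCDF/GeoTIFF (grid).

    Parameters
    ----------
    path
        ``.csv`` with ``date,tmin,tmax,prcp`` columns gives a
        :class:`ForcingSeries`; ``.nc`` gives :class:`GridStack` objects.
    variables
        Mapping from canonical names (``tmin``/``tmax``/``prcp``) to the
        variable names used in the file.  Defaults to identity.
    unit_conversions
        Optional ``{canonical: factor}`` multiplicative conversions for
        variables whose declared units are not already °C / mm.

    Returns
    -------
    ForcingSeries for CSV input.  For NetCDF: a dict of GridStacks keyed by
    canonical name, or the bare GridStack when exactly one variable was asked
    for.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_csv_forcing(path)
    if suffix in (".nc", ".nc4", ".cdf"):
        out = _read_netcdf(path, variables, unit_conversions)
        if len(out) == 1:
            return next(iter(out.values()))
        return out
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise ValueError(f"unrecognised forcing format {suffix!r} for {path}")


def read_grid(path, variables: dict[str, str] | None = None):
    """Read model-output or attribute grids (no unit coercion applied)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path)
    out = _read_netcdf(path, variables, None)
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def write_outputs(stack, path, format: str = "netcdf"):
    """Write one GridStack (or a dict of them) to NetCDF or GeoTIFF.

    Float32 payloads round-trip bit-identically through either format.  NetCDF
    files carry CF-style units/long_name attributes and the affine transform
    as a global attribute; GeoTIFF carries the transform in standard GeoTIFF
    tags (one band per day).
    """
    path = Path(path)
    stacks = list(stack.values()) if isinstance(stack, dict) else [stack]
    shapes = {s.data.shape[1:] for s in stacks}
    if len(shapes) != 1:
        raise GridAlignmentError(f"stacks have differing spatial shapes: {shapes}")
    if format == "netcdf":
        return _write_netcdf(stacks, path)
    if format == "geotiff":
        if len(stacks) != 1:
            raise ValueError("GeoTIFF output writes one variable per file")
        return _write_geotiff(stacks[0], path)
    raise ValueError(f"unknown format {format!r}; expected 'netcdf' or 'geotiff'")


def write_attributes(attrs: CellAttributes, path) -> Path:
    """Write a gridded CellAttributes bundle to a NetCDF file."""
    path = Path(path)
    shape = attrs.grid_shape
    if not shape:
        raise ValueError("write_attributes expects gridded (2-D) attributes")
    nrow, ncol = shape
    y, x = _y_x_coords(attrs.transform, nrow, ncol)

    def grid2d(value):
        return np.broadcast_to(np.asarray(value, dtype=float), shape)

    data_vars = {
        "latitude": (("y", "x"), grid2d(attrs.latitude), {"units": "degrees_north"}),
        "slope": (("y", "x"), grid2d(attrs.slope), {"units": "degrees"}),
        "aspect": (("y", "x"), grid2d(attrs.aspect), {"units": "degrees"}),
        "whc": (("y", "x"), grid2d(attrs.whc), {"units": "mm"}),
        "ndvi": (("doy", "y", "x"),
                 np.broadcast_to(attrs.ndvi_climatology.reshape(365, *(1,) * (2 - 0))
                                 if attrs.ndvi_climatology.ndim == 1
                                 else attrs.ndvi_climatology, (365, nrow, ncol)),
                 {"units": "1"}),
    }
    if attrs.snow_t50 is not None:
        data_vars["snow_t50"] = (("y", "x"), grid2d(attrs.snow_t50), {"units": "degC"})
    ds = xr.Dataset(data_vars, coords={"y": y, "x": x, "doy": np.arange(1, 366)})
    ds.attrs["transform"] = [float(v) for v in attrs.transform]
    ds.attrs["crs"] = attrs.crs
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")
    return path


def read_attributes(path) -> CellAttributes:
    """Read a CellAttributes bundle previously written by :func:`write_attributes`."""
    with xr.open_dataset(Path(path), engine="scipy", decode_times=False) as ds:
        ds.load()
    transform = Affine(*ds.attrs.get("transform", (1, 0, 0, 0, -1, 0)))
    required = {"latitude", "slope", "aspect", "whc", "ndvi"}
    missing = required - set(ds.data_vars)
    if missing:
        raise MissingVariableError(f"attribute file missing {sorted(missing)}")
    return CellAttributes(
        latitude=ds["latitude"].values, slope=ds["slope"].values,
        aspect=ds["aspect"].values, whc=ds["whc"].values,
        snow_t50=ds["snow_t50"].values if "snow_t50" in ds else None,
        ndvi_climatology=ds["ndvi"].values,
        transform=transform, crs=str(ds.attrs.get("crs", "")))
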