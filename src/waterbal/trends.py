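"""Per-pixel trends, normalized change index, and bivariate AET:CWD change vectors.

The analysis layer reduces annual AET/CWD totals to:

* ordinary least-squares slopes of annual totals on calendar year (mm/yr) —
  significance is deliberately not computed by default, since the interest is
  broad spatial patterns of change rather than inference;
* a normalized change index, ``(slope / period mean) * 10``, interpretable as
  the fractional change relative to the mean per decade;
* two-period means and their displacement in (CWD, AET) space: the change
  vector, whose Euclidean length is the intensity of combined change and
  whose quadrant (signs of the displacement) is the direction class;
* equal-count bivariate zones from marginal AET/CWD quantiles, and per
  category (ecoregion-style) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forcing_io import Affine, GridAlignmentError
from .simulator import AnnualSeries

__all__ = [
    "TrendResult", "ChangeVector", "DIRECTION_CLASSES", "pixel_trend",
    "trend_grid", "normalized_index", "period_means", "change_vector",
    "change_vector_grid", "bivariate_zones", "category_summary",
    "centroid_vectors",
]

#: direction-class code -> label; codes are what change_vector_grid stores
DIRECTION_CLASSES = {
    0: "no change",
    1: "+CWD+AET",
    2: "+CWD-AET",
    3: "-CWD+AET",
    4: "-CWD-AET",
}


@dataclass
class TrendResult:
    """OLS trend of an annual series: slope (mm/yr), intercept (mm, at year 0),
    period mean (mm), and the normalized index (fraction of mean per decade)."""

    slope: float
    intercept: float
    mean: float
    normalized_index: float
    n: int
    reason: str | None = None
    p_value: float | None = None


@dataclass
class ChangeVector:
    """Two-period displacement of a cell in (CWD, AET) space."""

    start: tuple[float, float]   # (cwd_mean1, aet_mean1)
    end: tuple[float, float]     # (cwd_mean2, aet_mean2)
    displacement: tuple[float, float]
    intensity: float             # Euclidean length, mm
    direction_class: str


def normalized_index(slope, period_mean):
    """(slope / mean) * 10 — fractional change relative to the mean per decade.

    Multiply by 100 to render as percent; NaN where the mean is 0.
    """
    slope = np.asarray(slope, dtype=float)
    mean = np.asarray(period_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean != 0.0, slope / mean * 10.0, np.nan)
    return out if out.ndim else float(out)


def pixel_trend(years, annual_values, compute_significance: bool = False) -> TrendResult:
    """OLS trend of one pixel's annual totals on calendar year.

    Missing (NaN) years are dropped pairwise; fewer than 3 remaining points
    gives a sentinel result with a reason.
    """
    years = np.asarray(years, dtype=float)
    vals = np.asarray(annual_values, dtype=float)
    ok = np.isfinite(years) & np.isfinite(vals)
    years, vals = years[ok], vals[ok]
    n = len(years)
    if n < 3:
        return TrendResult(np.nan, np.nan, np.nan, np.nan, n,
                           reason=f"only {n} non-missing year(s); need >= 3")
    xm = years.mean()
    ym = vals.mean()
    dx = years - xm
    slope = float(np.dot(dx, vals - ym) / np.dot(dx, dx))
    intercept = float(ym - slope * xm)
    p = None
    if compute_significance:
        p = float(stats.linregress(years, vals).pvalue)
    return TrendResult(slope, intercept, float(ym),
                       float(normalized_index(slope, ym)), n, p_value=p)


def trend_grid(years, values) -> dict[str, np.ndarray]:
    """Vectorised per-pixel OLS over a (n_years, nrow, ncol) array.

    Returns grids of slope, intercept, mean, normalized_index, and n (count
    of non-missing years); pixels with < 3 non-missing years are NaN.
    """
    years = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.shape[0] != len(years):
        raise ValueError(f"values first axis {v.shape[0]} != len(years) {len(years)}")
    ok = np.isfinite(v)
    n = ok.sum(axis=0)
    x = years.reshape(-1, *([1] * (v.ndim - 1)))
    xs = np.where(ok, x, 0.0)
    ys = np.where(ok, v, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        xm = xs.sum(axis=0) / n
        ym = ys.sum(axis=0) / n
        sxx = (np.where(ok, (x - xm) ** 2, 0.0)).sum(axis=0)
        sxy = (np.where(ok, (x - xm) * (v - ym), 0.0)).sum(axis=0)
        slope = sxy / sxx
    slope = np.where(n >= 3, slope, np.nan)
    mean = np.where(n >= 3, ym, np.nan)
    intercept = np.where(n >= 3, ym - slope * xm, np.nan)
    return {"slope": slope, "intercept": intercept, "mean": mean,
            "normalized_index": normalized_index(slope, mean), "n": n}


def period_means(years, values, period1, period2):
    """Arithmetic means of annual values over two year ranges (inclusive).

    ``period1``/``period2`` are (start, end) tuples; raises if either period
    selects no years.
    """
    years = np.asarray(years)
    v = np.asarray(values, dtype=float)
    out = []
    for lo, hi in (period1, period2):
        sel = (years >= lo) & (years <= hi)
        if not sel.any():
            raise ValueError(f"period {lo}-{hi} selects no years "
                             f"(available {years.min()}..{years.max()})")
        out.append(np.nanmean(v[sel], axis=0))
    return out[0], out[1]


def _direction_code(dcwd, daet):
    """Quadrant code from displacement signs.

    A zero component counts as increasing (documented tie-break); the zero
    vector is class 0, "no change".
    """
    dcwd = np.asarray(dcwd, dtype=float)
    daet = np.asarray(daet, dtype=float)
    code = np.where(dcwd >= 0,
                    np.where(daet >= 0, 1, 2),
                    np.where(daet >= 0, 3, 4))
    code = np.where((dcwd == 0) & (daet == 0), 0, code)
    return np.where(np.isfinite(dcwd) & np.isfinite(daet), code, -1).astype(np.int64)


def change_vector(mean1_cwd, mean1_aet, mean2_cwd, mean2_aet) -> ChangeVector:
    """Change vector between two period means of one cell (CWD horizontal,
    AET vertical); intensity is the Euclidean distance between endpoints."""
    dcwd = mean2_cwd - mean1_cwd
    daet = mean2_aet - mean1_aet
    intensity = float(np.hypot(dcwd, daet))
    code = int(_direction_code(dcwd, daet))
    return ChangeVector((float(mean1_cwd), float(mean1_aet)),
                        (float(mean2_cwd), float(mean2_aet)),
                        (float(dcwd), float(daet)), intensity,
                        DIRECTION_CLASSES.get(code, "nodata"))


def change_vector_grid(mean1_cwd, mean1_aet, mean2_cwd, mean2_aet) -> dict[str, np.ndarray]:
    """Gridded change vectors; returns dcwd, daet, intensity, direction_code."""
    dcwd = np.asarray(mean2_cwd, float) - np.asarray(mean1_cwd, float)
    daet = np.asarray(mean2_aet, float) - np.asarray(mean1_aet, float)
    return {"dcwd": dcwd, "daet": daet, "intensity": np.hypot(dcwd, daet),
            "direction_code": _direction_code(dcwd, daet)}


def bivariate_zones(mean_aet, mean_cwd, n_zones: int = 9) -> np.ndarray:
    """Equal-count bivariate zone labels from marginal AET/CWD quantile bins.

    ``n_zones`` must be a perfect square k²; a cell's label is
    ``aet_bin * k + cwd_bin`` (0-based).  Values equal to a bin edge fall in
    the lower bin; invalid (NaN) cells get label -1.
    """
    k = int(round(np.sqrt(n_zones)))
    if k * k != n_zones or k < 1:
        raise ValueError(f"n_zones must be a perfect square, got {n_zones}")
    aet = np.asarray(mean_aet, dtype=float)
    cwd = np.asarray(mean_cwd, dtype=float)
    if aet.shape != cwd.shape:
        raise GridAlignmentError(f"AET shape {aet.shape} != CWD shape {cwd.shape}")
    valid = np.isfinite(aet) & np.isfinite(cwd)
    if not valid.any():
        raise ValueError("all cells are nodata")

    def bins(values):
        if k == 1:
            return np.zeros(values.shape, dtype=np.int64)
        edges = np.quantile(values[valid], np.arange(1, k) / k)
        return np.searchsorted(edges, values, side="left").astype(np.int64)

    labels = bins(aet) * k + bins(cwd)
    return np.where(valid, labels, -1)


def category_summary(values: dict[str, np.ndarray], category_mask,
                     quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95)
                     ) -> pd.DataFrame:
    """Distributional summaries of value grids within each category of a mask.

    ``values`` maps variable name to a 2-D grid aligned with ``category_mask``
    (integer or string labels; NaN / negative labels are ignored).  Returns a
    tidy frame with one row per (category, variable): count, mean, and the
    requested quantiles.
    """
    mask = np.asarray(category_mask)
    rows = []
    for name, grid in values.items():
        grid = np.asarray(grid, dtype=float)
        if grid.shape != mask.shape:
            raise GridAlignmentError(
                f"values[{name!r}] shape {grid.shape} != mask shape {mask.shape}")
        flat_mask = mask.ravel()
        flat = grid.ravel()
        if flat_mask.dtype.kind in "fiu":
            valid_cat = np.isfinite(flat_mask.astype(float)) & (flat_mask.astype(float) >= 0)
        else:
            valid_cat = flat_mask != ""
        for cat in pd.unique(flat_mask[valid_cat]):
            sel = (flat_mask == cat) & np.isfinite(flat)
            row = {"category": cat, "variable": name, "count": int(sel.sum()),
                   "mean": float(flat[sel].mean()) if sel.any() else np.nan}
            for q in quantiles:
                row[f"q{q:g}"] = float(np.quantile(flat[sel], q)) if sel.any() else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def centroid_vectors(annual: AnnualSeries, points, transform: Affine,
                     period1, period2) -> tuple[pd.DataFrame, int]:
    """Change vectors at point locations (nearest-cell extraction).

    ``annual`` must carry both "aet" and "cwd"; ``points`` is a sequence of
    (x, y) world coordinates (optionally (name, x, y)).  Out-of-bounds points
    are skipped with a warning; the skipped count is returned alongside the
    table.
    """
    import warnings as _w

    for need in ("aet", "cwd"):
        if need not in annual.data:
            raise KeyError(f"annual series lacks {need!r}")
    aet1, aet2 = period_means(annual.years, annual.data["aet"], period1, period2)
    cwd1, cwd2 = period_means(annual.years, annual.data["cwd"], period1, period2)
    nrow, ncol = aet1.shape
    rows = []
    skipped = 0
    for i, pt in enumerate(points):
        if len(pt) == 3:
            name, x, y = pt
        else:
            name, (x, y) = f"point_{i}", pt
        r, c = transform.rowcol(x, y)
        r, c = int(r), int(c)
        if not (0 <= r < nrow and 0 <= c < ncol):
            skipped += 1
            _w.warn(f"point {name} at ({x}, {y}) is outside the grid; skipped",
                    stacklevel=2)
            continue
        cv = change_vector(cwd1[r, c], aet1[r, c], cwd2[r, c], aet2[r, c])
        rows.append({"name": name, "x": x, "y": y, "row": r, "col": c,
                     "cwd_mean1": cv.start[0], "aet_mean1": cv.start[1],
                     "cwd_mean2": cv.end[0], "aet_mean2": cv.end[1],
                     "dcwd": cv.displacement[0], "daet": cv.displacement[1],
                     "intensity": cv.intensity, "direction": cv.direction_class})
    return pd.DataFrame(rows), skipped
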