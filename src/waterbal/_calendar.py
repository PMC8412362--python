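"""Daily calendar handling for Gregorian ("standard") and 365-day ("noleap") time axes.

Daymet-style forcing uses a 365-day no-leap calendar; synthetic or station data may
be Gregorian.  Both are represented by :class:`DailyIndex`, a plain
(year, month, day) triple of integer arrays plus a calendar tag, so that no
third-party calendar library is needed.  Gregorian arithmetic delegates to pandas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STANDARD = "standard"
NOLEAP = "noleap"
CALENDARS = (STANDARD, NOLEAP)

_MONTH_DAYS_NOLEAP = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31],
                              dtype=np.int64)
_CUM_NOLEAP = np.concatenate(([0], np.cumsum(_MONTH_DAYS_NOLEAP)))  # length 13

# Day-of-year of Oct 1 in a no-leap year (water-year start).
_OCT1_DOY_NOLEAP = int(_CUM_NOLEAP[9] + 1)  # 274


class CalendarGapError(ValueError):
    """A daily index has missing or out-of-order days."""


def _parse_date(date) -> tuple[int, int, int]:
    """Accept 'YYYY-MM-DD', a (y, m, d) tuple, or anything pandas can parse."""
    if isinstance(date, tuple):
        y, m, d = date
        return int(y), int(m), int(d)
    ts = pd.Timestamp(date)
    return ts.year, ts.month, ts.day


def _noleap_ordinal(years, months, days):
    """Days since 0000-01-01 in a perpetual 365-day calendar (vectorised)."""
    years = np.asarray(years, dtype=np.int64)
    months = np.asarray(months, dtype=np.int64)
    days = np.asarray(days, dtype=np.int64)
    return years * 365 + _CUM_NOLEAP[months - 1] + (days - 1)


def _noleap_from_ordinal(ordinals):
    ordinals = np.asarray(ordinals, dtype=np.int64)
    years = ordinals // 365
    doy = ordinals % 365  # 0-based
    months = np.searchsorted(_CUM_NOLEAP, doy, side="right")  # 1..12
    days = doy - _CUM_NOLEAP[months - 1] + 1
    return years, months, days


@dataclass(frozen=True, eq=False)
class DailyIndex:
    """An immutable daily time axis.

    Parameters
    ----------
    years, months, days
        Integer arrays of equal length.
    calendar
        ``"standard"`` (Gregorian, leap days present) or ``"noleap"``
        (fixed 365-day years, no Feb 29).
    """

    years: np.ndarray
    months: np.ndarray
    days: np.ndarray
    calendar: str = STANDARD

    def __post_init__(self):
        if self.calendar not in CALENDARS:
            raise ValueError(f"unknown calendar {self.calendar!r}; expected one of {CALENDARS}")
        for name in ("years", "months", "days"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        n = len(self.years)
        if len(self.months) != n or len(self.days) != n:
            raise ValueError("years/months/days must have equal length")
        if self.calendar == NOLEAP and np.any((self.months == 2) & (self.days == 29)):
            raise ValueError("Feb 29 is not a valid no-leap date")

    # -- construction ----------------------------------------------------

    @classmethod
    def date_range(cls, start, n_days: int, calendar: str = STANDARD) -> "DailyIndex":
        y, m, d = _parse_date(start)
        if calendar == NOLEAP:
            ords = _noleap_ordinal(y, m, d) + np.arange(n_days, dtype=np.int64)
            yy, mm, dd = _noleap_from_ordinal(ords)
            return cls(yy, mm, dd, NOLEAP)
        idx = pd.date_range(pd.Timestamp(year=y, month=m, day=d), periods=n_days, freq="D")
        return cls.from_pandas(idx)

    @classmethod
    def from_pandas(cls, idx: pd.DatetimeIndex) -> "DailyIndex":
        return cls(idx.year.to_numpy(), idx.month.to_numpy(), idx.day.to_numpy(), STANDARD)

    # -- basics ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.years)

    def __getitem__(self, key) -> "DailyIndex":
        return DailyIndex(self.years[key], self.months[key], self.days[key], self.calendar)

    def equals(self, other: "DailyIndex") -> bool:
        return (self.calendar == other.calendar
                and np.array_equal(self.years, other.years)
                and np.array_equal(self.months, other.months)
                and np.array_equal(self.days, other.days))

    def to_pandas(self) -> pd.DatetimeIndex:
        if self.calendar != STANDARD:
            raise ValueError("only the standard calendar converts to a DatetimeIndex")
        return pd.DatetimeIndex(pd.to_datetime(
            pd.DataFrame({"year": self.years, "month": self.months, "day": self.days})))

    @property
    def first_date(self) -> str:
        return f"{self.years[0]:04d}-{self.months[0]:02d}-{self.days[0]:02d}"

    def isoformat(self) -> np.ndarray:
        """Array of 'YYYY-MM-DD' strings (for error messages and CSV output)."""
        return np.array([f"{y:04d}-{m:02d}-{d:02d}"
                         for y, m, d in zip(self.years, self.months, self.days)])

    # -- ordinals and validation -----------------------------------------

    @property
    def ordinals(self) -> np.ndarray:
        """Integer day numbers on this index's own calendar (strictly +1 per day)."""
        if self.calendar == NOLEAP:
            return _noleap_ordinal(self.years, self.months, self.days)
        return self.to_pandas().asi8 // 86_400_000_000_000

    def validate_contiguous(self) -> None:
        """Raise :class:`CalendarGapError` unless the index is gap-free daily."""
        ords = self.ordinals
        diffs = np.diff(ords)
        if np.any(diffs != 1):
            i = int(np.argmax(diffs != 1))
            if diffs[i] < 1:
                raise CalendarGapError(
                    f"daily index not strictly increasing at position {i + 1} "
                    f"({self.isoformat()[i + 1]})")
            missing_ord = ords[i] + 1
            if self.calendar == NOLEAP:
                y, m, d = _noleap_from_ordinal(missing_ord)
                missing = f"{int(y):04d}-{int(m):02d}-{int(d):02d}"
            else:
                missing = str((pd.Timestamp(0) + pd.Timedelta(days=int(missing_ord))).date())
            raise CalendarGapError(f"daily index has a gap: missing {missing}")

    # -- derived day labels ----------------------------------------------

    @property
    def day_of_year(self) -> np.ndarray:
        """1-based day of year (1..365 no-leap, 1..366 standard)."""
        if self.calendar == NOLEAP:
            return _CUM_NOLEAP[self.months - 1] + self.days
        return self.to_pandas().dayofyear.to_numpy()

    @property
    def climatology_index(self) -> np.ndarray:
        """0-based index into a 365-entry daily climatology.

        In Gregorian leap years Feb 29 maps to the Feb 28 entry and later days
        shift back by one, so every day of any year lands in 0..364.
        """
        doy = self.day_of_year
        if self.calendar == NOLEAP:
            return doy - 1
        leap = pd.Series(self.years).map(
            lambda y: (y % 4 == 0 and y % 100 != 0) or y % 400 == 0).to_numpy()
        idx = doy - 1
        shift = leap & (doy >= 60)  # Feb 29 is doy 60 in a leap year
        return np.where(shift, idx - 1, idx)

    def water_year(self) -> tuple[np.ndarray, np.ndarray]:
        """(water-year label, 1-based day of water year) for every day.

        Water years run Oct 1 – Sep 30 and are labelled by the ending calendar
        year: 2000-10-01 is day 1 of water year 2001.
        """
        labels = self.years + (self.months >= 10).astype(np.int64)
        if self.calendar == NOLEAP:
            start_ord = (labels - 1) * 365 + (_OCT1_DOY_NOLEAP - 1)
            dowy = self.ordinals - start_ord + 1
        else:
            starts = pd.to_datetime(pd.DataFrame(
                {"year": labels - 1, "month": 10, "day": 1}))
            start_ord = starts.astype("int64").to_numpy() // 86_400_000_000_000
            dowy = self.ordinals - start_ord + 1
        return labels, dowy

    def days_in_year(self, year: int) -> int:
        if self.calendar == NOLEAP:
            return 365
        return 366 if ((year % 4 == 0 and year % 100 != 0) or year % 400 == 0) else 365

    def days_in_water_year(self, label: int) -> int:
        if self.calendar == NOLEAP:
            return 365
        # A water year contains Feb 29 iff its ending calendar year is leap.
        return 366 if self.days_in_year(label) == 366 else 365
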