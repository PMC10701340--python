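"""Seasonality of daily oceanographic forcing and productivity.

Each foraging ground has a region-specific daily forcing metric — a
coastal upwelling transport index (CUTI) off California, a nearshore/
offshore SST-difference upwelling index in the South Taranaki Bight,
box-averaged zonal wind stress in the Corcovado Gulf.  Seasonality is
characterized by accumulating the metric within each "season year"
(January-start in the Northern Hemisphere, July-start in the Southern,
so austral summers are not split), averaging the cumulative curves into
a climatological mean, and measuring how much of the year the middle
50% (or 80%) of the annual accumulation occupies: the 50% window runs
from the day the climatological mean reaches 25% of its annual total to
the day it reaches 75% (the 80% window: 10% to 90%).  Short windows
mean concentrated, strongly seasonal forcing.

Biological productivity is summarized by a monthly chlorophyll-a
climatology, and the freshwater influence on productivity by a Pearson
correlation between sea-surface salinity and chlorophyll-a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats


class DateMismatch(ValueError):
    """Two daily series do not share the same date index."""


class UndefinedWindow(ValueError):
    """Accumulation window undefined (nonpositive final accumulation)."""


@dataclass
class DailySeries:
    """Date-indexed daily forcing values with region/hemisphere metadata."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    region: str = ""
    hemisphere: str = "N"  # "N" or "S"
    units: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.dates),):
            raise ValueError("values and dates must have equal length")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        if self.hemisphere not in ("N", "S"):
            raise ValueError(f"hemisphere must be 'N' or 'S', got {self.hemisphere!r}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.region)

    @classmethod
    def from_csv(cls, path, region: str = "", hemisphere: str = "N", units: str = ""):
        """Read a (date,value) CSV, e.g. an ERDDAP-style export."""
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(
            dates=pd.DatetimeIndex(df["date"]),
            values=df["value"].to_numpy(float),
            region=region,
            hemisphere=hemisphere,
            units=units,
        )


@dataclass
class SeasonYearCurve:
    """Within-year cumulative sum of a daily series on a 365-day grid."""

    season_year: int
    cumulative: np.ndarray  # day 1..365 (leap days dropped)
    missing_days: int = 0

    def __post_init__(self) -> None:
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.cumulative.shape != (365,):
            raise ValueError("season-year curve must have 365 days")


@dataclass(frozen=True)
class AccumulationWindow:
    """Fractional accumulation interval on a climatological curve.

    ``start_day``/``end_day`` are (possibly fractional) days of the
    season year at which the curve crosses the lower/upper thresholds;
    for the 50% window these are the 25% and 75% crossings.
    """

    fraction: float
    start_day: float
    end_day: float

    @property
    def length_days(self) -> float:
        return self.end_day - self.start_day

    @property
    def start_label(self) -> int:
        """Whole-day label for reports (round half-up)."""
        return int(np.floor(self.start_day + 0.5))

    @property
    def end_label(self) -> int:
        return int(np.floor(self.end_day + 0.5))


def season_year(dates: pd.DatetimeIndex, hemisphere: str) -> np.ndarray:
    """Season-year label per date: calendar year (N) or July-start year (S).

    Southern-Hemisphere season year Y runs 1 July Y .. 30 June Y+1, so a
    date before 1 July belongs to the previous season year.
    """
    years = dates.year.to_numpy()
    if hemisphere == "S":
        return np.where(dates.month >= 7, years, years - 1)
    return years


def season_year_split(
    series: DailySeries,
    max_missing_fraction: float = 0.5,
) -> tuple[dict[int, SeasonYearCurve], list[int]]:
    """Split a daily series into within-season-year cumulative curves.

    Missing days (absent dates or NaN values) contribute zero to the
    cumulative sum and are counted in each curve's ``missing_days``;
    Feb 29 is dropped for a uniform 365-day grid.  Season years missing
    more than ``max_missing_fraction`` of days, and the (possibly
    partial) first/last season years with no data at their boundaries,
    are excluded and reported in the second return value.
    """
    s = series.to_series()
    s = s[~((s.index.month == 2) & (s.index.day == 29))]
    labels = season_year(s.index, series.hemisphere)
    curves: dict[int, SeasonYearCurve] = {}
    excluded: list[int] = []
    for year in np.unique(labels):
        chunk = s[labels == year]
        start = pd.Timestamp(year=year, month=1 if series.hemisphere == "N" else 7, day=1)
        grid = pd.date_range(start, periods=366, freq="D")
        grid = grid[~((grid.month == 2) & (grid.day == 29))][:365]
        vals = chunk.reindex(grid).to_numpy(float)
        missing = int(np.isnan(vals).sum())
        if missing > max_missing_fraction * 365:
            excluded.append(int(year))
            continue
        curves[int(year)] = SeasonYearCurve(
            season_year=int(year),
            cumulative=np.cumsum(np.nan_to_num(vals)),
            missing_days=missing,
        )
    return curves, excluded


def climatological_mean(curves: dict[int, SeasonYearCurve] | list[SeasonYearCurve]) -> np.ndarray:
    """Day-wise mean cumulative curve across season years."""
    if isinstance(curves, dict):
        curves = list(curves.values())
    if len(curves) < 2:
        raise ValueError("need >= 2 season-year curves for a climatological mean")
    return np.mean([c.cumulative for c in curves], axis=0)


def accumulation_window(mean_curve: np.ndarray, fraction: float = 0.5) -> AccumulationWindow:
    """Fractional accumulation window of a climatological cumulative curve.

    The lower/upper thresholds are (1 -+ fraction)/2 of the final
    accumulation (25%/75% for the 50% window, 10%/90% for the 80%).
    Crossing days are located by linear interpolation on the piecewise-
    linear curve through (0, 0), (1, C_1), ..., (365, C_365).  When both
    crossings fall within the same one-day segment the daily data cannot
    resolve a sub-day window and a zero-length window at that day is
    reported (the single-day-impulse case).
    """
    c = np.asarray(mean_curve, dtype=float)
    total = c[-1]
    if not total > 0:
        raise UndefinedWindow(f"final accumulation must be positive, got {total}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    lo_q = (1 - fraction) / 2 * total
    hi_q = (1 + fraction) / 2 * total
    days = np.arange(0, 366, dtype=float)
    curve = np.concatenate([[0.0], c])
    start = _crossing_day(days, curve, lo_q)
    end = _crossing_day(days, curve, hi_q)
    if int(np.ceil(start)) == int(np.ceil(end)) and not np.isclose(start, np.floor(start)):
        day = float(np.ceil(start))
        return AccumulationWindow(fraction=fraction, start_day=day, end_day=day)
    return AccumulationWindow(fraction=fraction, start_day=start, end_day=end)


def _crossing_day(days: np.ndarray, curve: np.ndarray, q: float) -> float:
    """First day at which the piecewise-linear curve reaches level q."""
    above = np.nonzero(curve >= q)[0]
    if above.size == 0:
        return float(days[-1])
    k = above[0]
    if k == 0 or curve[k] == curve[k - 1]:
        return float(days[k])
    t = (q - curve[k - 1]) / (curve[k] - curve[k - 1])
    return float(days[k - 1] + t)


def upwelling_index_sst(
    nearshore: DailySeries, offshore: DailySeries, positive_when_nearshore_colder: bool = True
) -> DailySeries:
    """SST-difference upwelling index: offshore minus nearshore.

    Upwelled water is cold, so a colder nearshore station relative to
    offshore indicates active upwelling; with the default sign
    convention the index is positive then.  Set the flag False for the
    opposite (nearshore - offshore) convention.
    """
    if len(nearshore.dates) != len(offshore.dates) or (nearshore.dates != offshore.dates).any():
        raise DateMismatch("nearshore and offshore series must share dates")
    diff = offshore.values - nearshore.values
    if not positive_when_nearshore_colder:
        diff = -diff
    return DailySeries(
        dates=nearshore.dates,
        values=diff,
        region=nearshore.region,
        hemisphere=nearshore.hemisphere,
        units="degC difference",
    )


def box_average(
    field_da: xr.DataArray,
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    region: str = "",
    hemisphere: str = "N",
) -> DailySeries:
    """Unweighted spatial mean of a gridded (time, lat, lon) field in a box.

    Grid cells whose centers fall inside the closed box are averaged per
    time step; missing cells are excluded from each day's mean.  Ranges
    may be given in either order (e.g. the Corcovado box, latitude -42
    to -45, longitude -73 to -75).
    """
    lat_lo, lat_hi = sorted(lat_range)
    lon_lo, lon_hi = sorted(lon_range)
    lat_name = "lat" if "lat" in field_da.dims else "latitude"
    lon_name = "lon" if "lon" in field_da.dims else "longitude"
    sub = field_da.where(
        (field_da[lat_name] >= lat_lo) & (field_da[lat_name] <= lat_hi)
        & (field_da[lon_name] >= lon_lo) & (field_da[lon_name] <= lon_hi),
        drop=True,
    )
    if sub.sizes.get(lat_name, 0) == 0 or sub.sizes.get(lon_name, 0) == 0:
        raise ValueError("box does not intersect the grid")
    mean = sub.mean(dim=[lat_name, lon_name], skipna=True)
    return DailySeries(
        dates=pd.DatetimeIndex(mean["time"].values),
        values=mean.values,
        region=region,
        hemisphere=hemisphere,
        units=str(field_da.attrs.get("units", "")),
    )


def open_gridded(path) -> xr.Dataset:
    """Open a CF-convention NetCDF extract (classic NetCDF-3 format)."""
    return xr.open_dataset(path, engine="scipy")


@dataclass
class MonthlyClimatology:
    """Mean annual cycle of a monthly series plus per-year traces."""

    monthly_mean: np.ndarray  # 12 values, Jan..Dec
    per_year: pd.DataFrame  # index month 1..12, one column per year

    @property
    def peak_month(self) -> int:
        return int(np.nanargmax(self.monthly_mean)) + 1


def monthly_climatology(series: pd.Series) -> MonthlyClimatology:
    """Climatological mean per calendar month of a monthly series."""
    if len(series) < 12:
        raise ValueError("need at least 12 months")
    df = pd.DataFrame({"value": series.to_numpy(float)}, index=pd.DatetimeIndex(series.index))
    df["month"] = df.index.month
    df["year"] = df.index.year
    per_year = df.pivot_table(index="month", columns="year", values="value")
    per_year = per_year.reindex(range(1, 13))
    return MonthlyClimatology(
        monthly_mean=per_year.mean(axis=1).to_numpy(float),
        per_year=per_year,
    )


def salinity_chl_correlation(sss: pd.Series, chl: pd.Series) -> tuple[float, float]:
    """Pearson correlation between date-aligned salinity and chlorophyll-a.

    Returns (r, two-sided p).  Pairs with a missing value in either
    series are dropped; a negative r indicates fresher water coinciding
    with higher productivity (the freshwater-influence signature).
    """
    joined = pd.concat({"sss": sss, "chl": chl}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 aligned, non-missing pairs")
    if joined["sss"].std() == 0 or joined["chl"].std() == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    r, p = stats.pearsonr(joined["sss"], joined["chl"])
    return float(r), float(p)
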