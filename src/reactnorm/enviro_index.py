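"""Weather-derived environmental indices: growing degree days and photothermal time.

Daily growing degree days (GDD, degC*day) accumulate temperature between a
base (10 degC) and a ceiling (37.8 degC), the convention for sorghum
flowering time; photothermal time (PTT, degC*day*h) multiplies daily GDD by
astronomical day length.  A window index averages the daily values over a
fixed interval of days after planting (day 1 = the day after planting), and
a grid search over windows finds the one whose index across environments
best correlates with the observed environmental means.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "DailyWeather",
    "EnvIndexValue",
    "daily_gdd",
    "day_length",
    "window_index",
    "window_search",
]

GDD_BASE = 10.0
GDD_CEILING = 37.8


@dataclass
class DailyWeather:
    """Daily Tmax/Tmin series for one site, with coordinates.

    ``frame`` is indexed by calendar date with columns tmax, tmin and an
    optional day_length (hours) overriding the astronomical value.
    """

    site: str
    latitude: float
    longitude: float
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise InvalidArgumentError("latitude outside [-90, 90]")
        f = self.frame
        if not {"tmax", "tmin"} <= set(f.columns):
            raise InvalidArgumentError("frame needs tmax and tmin columns")
        if (f["tmax"] < f["tmin"]).any():
            bad = f.index[f["tmax"] < f["tmin"]][:3].tolist()
            raise InvalidArgumentError(f"tmax < tmin on dates {bad}")


@dataclass
class EnvIndexValue:
    environment: str
    family: str
    start_day: int
    end_day: int
    value: float
    planting_date: dt.date


def daily_gdd(tmax, tmin, base: float = GDD_BASE, ceiling: float = GDD_CEILING):
    """Daily growing degree days with separate clamping of Tmax and Tmin.

    Both temperatures are clamped into [base, ceiling] before averaging:
    gdd = (clamp(tmax) + clamp(tmin)) / 2 - base, never negative.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise InvalidArgumentError("tmax < tmin")
    hi = np.clip(tmax, base, ceiling)
    lo = np.clip(tmin, base, ceiling)
    out = (hi + lo) / 2.0 - base
    return float(out) if out.ndim == 0 else out


def day_length(latitude: float, date: dt.date) -> float:
    """Astronomical day length (h) from solar declination.

    Sunrise/sunset at solar zenith 90.833 deg (refraction + solar radius);
    polar day/night clamp to 24/0 h.  Declination uses the Spencer Fourier
    series in the day-of-year angle.
    """
    doy = date.timetuple().tm_yday
    g = 2.0 * np.pi * (doy - 1) / 365.0
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    phi = np.deg2rad(latitude)
    cos_h = ((np.cos(np.deg2rad(90.833)) - np.sin(phi) * np.sin(decl))
             / (np.cos(phi) * np.cos(decl)))
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return float(2.0 * np.rad2deg(np.arccos(cos_h)) / 15.0)


def _daily_values(weather: DailyWeather, dates: pd.DatetimeIndex,
                  family: str) -> np.ndarray:
    f = weather.frame
    missing = dates.difference(f.index)
    if len(missing):
        raise CoverageError(
            f"site {weather.site}: weather missing for "
            f"{[d.date().isoformat() for d in missing[:5]]}"
            + ("..." if len(missing) > 5 else ""))
    sub = f.loc[dates]
    g = daily_gdd(sub["tmax"].to_numpy(), sub["tmin"].to_numpy())
    if family == "GDD":
        return g
    if family == "PTT":
        if "day_length" in sub.columns and sub["day_length"].notna().all():
            dl = sub["day_length"].to_numpy(dtype=float)
        else:
            dl = np.array([day_length(weather.latitude, d.date()) for d in dates])
        return g * dl
    raise InvalidArgumentError(f"unknown index family {family!r}")


def window_index(
    weather: DailyWeather,
    planting_date: dt.date,
    start_day: int,
    end_day: int,
    family: str = "PTT",
    environment: str | None = None,
    aggregate: str = "mean",
) -> EnvIndexValue:
    """Index over an inclusive window of days after planting (planting = day 0).

    Daily values are GDD or GDD x day length (PTT); the window statistic is
    their mean by default (so windows of different lengths are comparable) or
    their sum when ``aggregate="sum"``.
    """
    if not 0 <= start_day <= end_day:
        raise InvalidArgumentError("require 0 <= start_day <= end_day")
    if aggregate not in ("mean", "sum"):
        raise InvalidArgumentError(f"unknown aggregate {aggregate!r}")
    start = pd.Timestamp(planting_date) + pd.Timedelta(days=start_day)
    dates = pd.date_range(start, periods=end_day - start_day + 1, freq="D")
    vals = _daily_values(weather, dates, family)
    value = float(vals.mean() if aggregate == "mean" else vals.sum())
    return EnvIndexValue(environment=environment or weather.site, family=family,
                         start_day=start_day, end_day=end_day, value=value,
                         planting_date=planting_date)


def window_search(
    weathers: dict[str, DailyWeather],
    planting_dates: dict[str, dt.date],
    observed_env_means: dict[str, float],
    family: str = "PTT",
    start_grid=range(0, 61, 3),
    end_grid=range(0, 91, 3),
    aggregate: str = "mean",
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Grid search for the window whose index best tracks the observed means.

    Scores every (start, end) pair with start <= end by the Pearson r between
    the window index across environments and the observed environmental
    means.  Returns the winning window (max |r|; ties to the earliest start,
    then the shortest window) and the full correlation surface.
    """
    envs = sorted(observed_env_means)
    if len(envs) < 3:
        raise InvalidArgumentError("window search needs >=3 environments")
    means = np.array([observed_env_means[e] for e in envs])
    rows = []
    for s in start_grid:
        for e in end_grid:
            if e < s:
                continue
            vals = np.array([
                window_index(weathers[env], planting_dates[env], s, e, family,
                             aggregate=aggregate).value
                for env in envs])
            if np.std(vals) == 0 or np.std(means) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(vals, means)[0, 1])
            rows.append((s, e, r))
    surface = pd.DataFrame(rows, columns=["start", "end", "r"])
    ranked = surface.assign(absr=surface["r"].abs(),
                            length=surface["end"] - surface["start"])
    ranked = ranked.sort_values(["absr", "start", "length"],
                                ascending=[False, True, True], kind="stable")
    top = ranked.iloc[0]
    return (int(top["start"]), int(top["end"])), surface
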