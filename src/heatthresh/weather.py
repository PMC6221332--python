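"""Derived meteorological factors for heatwave-threshold analysis.

Transforms raw daily/hourly station weather records into the 19 derived
factors used as candidate heatwave-exposure metrics: same-day temperatures
(Tmin, Tavg, Tmax), daytime (noon-6 PM) mean temperature, multi-day trailing
means of Tmax and of the daytime mean, day-to-day temperature gaps, the raw
humidity / precipitation / wind / solar variables, and two composite
temperature-humidity indices (the NWS heat index and Thom's discomfort
index).

Daily input schema (one row per station-day, temperatures in deg C):
``station, date, tmin, tavg, tmax, rhum, precip, wind, sol_max, sol_vol``.
Optional hourly schema: ``station, date, hour, temp`` with hour 0-23 marking
the start of the observation hour.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 19 derived factor columns, in canonical order.
FEATURE_COLUMNS = [
    "Tmin",
    "Tavg",
    "Tavg1218",
    "AvgTavg1218Lag1",
    "AvgTavg1218Lag2",
    "AvgTavg1218Lag3",
    "Tmax",
    "AvgTmaxLag1",
    "AvgTmaxLag2",
    "AvgTmaxLag3",
    "TmaxGap",
    "TavgGap",
    "Whum",
    "Wpc",
    "Wwind",
    "WsolMAX",
    "WsolVOL",
    "Nindex1",
    "Nindex2",
]

#: Daytime window: hourly observations stamped 12:00 through 17:00 inclusive,
#: i.e. the half-open interval [noon, 6 PM) with stamps marking hour starts.
DAYTIME_HOURS = (12, 13, 14, 15, 16, 17)


def _check_rh(rh) -> np.ndarray:
    rh = np.asarray(rh, dtype=float)
    bad = (rh < 0) | (rh > 100)
    if np.any(bad & ~np.isnan(rh)):
        raise ValueError("relative humidity outside [0, 100]")
    return rh


def heat_index(t_f, rh, *, use_simple_below_80: bool = False):
    """NWS heat index (Rothfusz regression) in deg F.

    Parameters
    ----------
    t_f : array_like
        Air temperature in deg F.
    rh : array_like
        Relative humidity in percent, within [0, 100].
    use_simple_below_80 : bool
        If True, apply the NWS simple-average fallback formula when the
        simple estimate is below 80 deg F. Off by default: the full
        regression is the defining formula here.

    Returns
    -------
    Scalar or ndarray of heat index values (deg F). The low-humidity
    subtraction applies for RH < 13 and 80 <= T <= 112; the high-humidity
    addition for RH > 85 and 80 <= T <= 87.
    """
    t = np.asarray(t_f, dtype=float)
    rh = _check_rh(rh)
    t, rh = np.broadcast_arrays(t, rh)

    hi = (
        -42.379
        + 2.04901523 * t
        + 10.14333127 * rh
        - 0.22475541 * t * rh
        - 0.00683783 * t * t
        - 0.05481717 * rh * rh
        + 0.00122874 * t * t * rh
        + 0.00085282 * t * rh * rh
        - 0.00000199 * t * t * rh * rh
    )

    # low-humidity adjustment (subtract)
    m1 = (rh < 13) & (t >= 80) & (t <= 112)
    if np.any(m1):
        adj1 = ((13.0 - rh) / 4.0) * np.sqrt(
            np.clip((17.0 - np.abs(t - 95.0)) / 17.0, 0.0, None)
        )
        hi = np.where(m1, hi - adj1, hi)
    # high-humidity adjustment (add)
    m2 = (rh > 85) & (t >= 80) & (t <= 87)
    if np.any(m2):
        adj2 = ((rh - 85.0) / 10.0) * ((87.0 - t) / 2.0)
        hi = np.where(m2, hi + adj2, hi)

    if use_simple_below_80:
        simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)
        hi = np.where(0.5 * (simple + t) < 80.0, simple, hi)

    if np.ndim(t_f) == 0 and np.ndim(rh) <= 1 and hi.ndim == 0:
        return float(hi)
    return hi


def discomfort_index(tc, rh):
    """Thom's discomfort index from temperature (deg C) and humidity (%).

    DI = 1.8*Tc - (1 - 0.01*RH)*(Tc - 14.3) + 32
    """
    tc = np.asarray(tc, dtype=float)
    rh = _check_rh(rh)
    out = 1.8 * tc - (1.0 - 0.01 * rh) * (tc - 14.3) + 32.0
    if out.ndim == 0:
        return float(out)
    return out


def daytime_mean(hourly_temp) -> float:
    """Mean temperature over the noon-6 PM window of one day.

    `hourly_temp` is a sequence of 24 values indexed by observation hour
    (0-23), or a mapping/Series keyed by hour. Any missing value within the
    window yields NaN (logged).
    """
    if isinstance(hourly_temp, pd.Series):
        vals = [hourly_temp.get(h, np.nan) for h in DAYTIME_HOURS]
    elif isinstance(hourly_temp, dict):
        vals = [hourly_temp.get(h, np.nan) for h in DAYTIME_HOURS]
    else:
        arr = np.asarray(hourly_temp, dtype=float)
        if arr.shape[0] != 24:
            raise ValueError(f"expected 24 hourly values, got {arr.shape[0]}")
        vals = arr[list(DAYTIME_HOURS)]
    vals = np.asarray(vals, dtype=float)
    if np.any(np.isnan(vals)):
        logger.debug("missing hour in daytime window; emitting NaN")
        return float("nan")
    return float(vals.mean())


def lagged_mean(series, k: int):
    """Trailing mean of days i-k .. i; the first k days are missing.

    k=0 is the identity. The index is assumed to be consecutive days.
    """
    if k < 0:
        raise ValueError("lag k must be >= 0")
    s = pd.Series(series, dtype=float) if not isinstance(series, pd.Series) else series.astype(float)
    if k == 0:
        return s.copy()
    return s.rolling(window=k + 1, min_periods=k + 1).mean()


def day_gap(series):
    """Signed day-to-day difference value(i) - value(i-1); first day missing."""
    s = pd.Series(series, dtype=float) if not isinstance(series, pd.Series) else series.astype(float)
    return s.diff()


def _check_consecutive(dates: pd.Series, station) -> None:
    d = pd.to_datetime(dates)
    gaps = d.diff().dt.days
    bad = gaps[(gaps.notna()) & (gaps != 1)]
    if len(bad):
        i = bad.index[0]
        raise ValueError(
            f"non-consecutive dates for station {station!r}: break before {d.loc[i].date()}"
        )


def _daytime_means(hourly: pd.DataFrame) -> pd.Series:
    """Per (station, date) daytime mean from a long hourly table."""
    win = hourly[hourly["hour"].isin(DAYTIME_HOURS)]
    counts = win.groupby(["station", "date"])["temp"].agg(["mean", "count"])
    out = counts["mean"].where(counts["count"] == len(DAYTIME_HOURS))
    n_bad = int((counts["count"] != len(DAYTIME_HOURS)).sum())
    if n_bad:
        logger.warning("daytime window incomplete on %d station-days; set to NaN", n_bad)
    return out


def build_feature_table(
    daily: pd.DataFrame, hourly: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Build the 19-column derived-factor table from raw station weather.

    Parameters
    ----------
    daily : DataFrame
        Columns ``station, date, tmin, tavg, tmax, rhum, precip, wind,
        sol_max, sol_vol`` (``station`` optional; a single implicit series
        is assumed when absent). Dates must be consecutive within each
        station series.
    hourly : DataFrame, optional
        Long table ``station, date, hour, temp`` supplying the daytime-mean
        temperature; when absent, Tavg1218 and its trailing means are NaN.

    Returns
    -------
    DataFrame with ``station, date`` plus the 19 factor columns. Lag-k
    columns are NaN for the first k days of each station series. Nindex1 is
    the heat index computed from the daily mean temperature (converted to
    deg F) and relative humidity; Nindex2 is the discomfort index from the
    same inputs in deg C.
    """
    df = daily.copy()
    if "station" not in df.columns:
        df["station"] = "_single"
        drop_station = True
    else:
        drop_station = False
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["station", "date"]).reset_index(drop=True)

    if hourly is not None:
        h = hourly.copy()
        if "station" not in h.columns:
            h["station"] = "_single"
        h["date"] = pd.to_datetime(h["date"])
        dtm = _daytime_means(h)
    else:
        dtm = None

    pieces = []
    for station, g in df.groupby("station", sort=False):
        _check_consecutive(g["date"], station)
        g = g.reset_index(drop=True)
        out = pd.DataFrame({"station": station, "date": g["date"]})
        out["Tmin"] = g["tmin"].astype(float).values
        out["Tavg"] = g["tavg"].astype(float).values
        if dtm is not None:
            key = pd.MultiIndex.from_arrays([out["station"], out["date"]])
            out["Tavg1218"] = dtm.reindex(key).to_numpy(dtype=float)
        else:
            out["Tavg1218"] = np.nan
        for k in (1, 2, 3):
            out[f"AvgTavg1218Lag{k}"] = lagged_mean(out["Tavg1218"], k).values
        out["Tmax"] = g["tmax"].astype(float).values
        for k in (1, 2, 3):
            out[f"AvgTmaxLag{k}"] = lagged_mean(out["Tmax"], k).values
        out["TmaxGap"] = day_gap(out["Tmax"]).values
        out["TavgGap"] = day_gap(out["Tavg"]).values
        out["Whum"] = g["rhum"].astype(float).values
        out["Wpc"] = g["precip"].astype(float).values
        out["Wwind"] = g["wind"].astype(float).values
        out["WsolMAX"] = g["sol_max"].astype(float).values
        out["WsolVOL"] = g["sol_vol"].astype(float).values
        tavg_f = 1.8 * out["Tavg"].values + 32.0
        out["Nindex1"] = heat_index(tavg_f, out["Whum"].values)
        out["Nindex2"] = discomfort_index(out["Tavg"].values, out["Whum"].values)
        pieces.append(out)

    res = pd.concat(pieces, ignore_index=True)
    if drop_station:
        res = res.drop(columns=["station"])
    return res
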