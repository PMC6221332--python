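"""Synthetic weather, morbidity, and center-day study panels.

The real inputs — Korean summer station weather and center-level counts of
heat-illness emergency visits — are not redistributable, so this module
generates stand-ins with the statistical structure the analysis assumes:

* a seasonal summer temperature curve plus AR(1) daily anomalies, a
  mid-afternoon-peaking diurnal cycle, humidity anticorrelated with the
  temperature anomaly, intermittent gamma-distributed rain, wind and solar
  radiation;
* standardized morbidity drawn from a hinge-spline model plus Gaussian
  noise (the generative counterpart of the least-squares fit);
* a center x day panel (74 centers x 521 days at full scale) with county
  populations, subgroup visit counts that add up exactly, and
  population-standardized outcomes.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mars import MarsModel
from .weather import build_feature_table

#: Surveillance windows of the source system, by year (start, end).
SURVEILLANCE_WINDOWS = {
    2011: ("2011-07-01", "2011-09-09"),
    2012: ("2012-06-01", "2012-09-06"),
    2013: ("2013-06-01", "2013-09-07"),
    2014: ("2014-06-01", "2014-09-06"),
    2015: ("2015-05-24", "2015-09-05"),
    2016: ("2016-05-23", "2016-09-21"),
}

#: Panel subgroup columns (whole-count plus the subcategory breakdowns).
PANEL_COUNT_COLUMNS = [
    "HWwhole",
    "HWyoung",
    "HWadult",
    "HWolder",
    "HWmale",
    "HWfemale",
    "HWdisch",
    "HWhospital",
    "HWjunjul",
    "HWaug",
    "HWin",
    "HWout",
]


def study_calendar(
    years,
    june_august: bool = True,
    overrides: dict[int, tuple[str, str]] | None = None,
) -> pd.DatetimeIndex:
    """Per-year study dates: June 1 - Aug 31 by default (92 days/year).

    ``overrides`` maps a year to an explicit (start, end) window, e.g. the
    source surveillance windows in :data:`SURVEILLANCE_WINDOWS`; with
    ``june_august`` set the window is additionally clipped to June-August.
    """
    overrides = overrides or {}
    pieces = []
    for year in years:
        if year in overrides:
            start, end = (pd.Timestamp(d) for d in overrides[year])
        else:
            start, end = pd.Timestamp(year, 6, 1), pd.Timestamp(year, 8, 31)
        if end < start:
            raise ValueError(f"year {year}: end {end.date()} before start {start.date()}")
        if june_august:
            start = max(start, pd.Timestamp(year, 6, 1))
            end = min(end, pd.Timestamp(year, 8, 31))
        if end >= start:
            pieces.append(pd.date_range(start, end, freq="D"))
    if not pieces:
        return pd.DatetimeIndex([], dtype="datetime64[ns]")
    return pieces[0].append(pieces[1:]) if len(pieces) > 1 else pieces[0]


@dataclass
class WeatherSimConfig:
    """Summer station-weather generator settings.

    Defaults emulate the Seoul-area summer climate summarized by the study
    variables (daily mean ~25 degC, maxima reaching the high 30s, humid):
    a cosine annual cycle peaking in early August, AR(1) anomalies, and a
    diurnal range of ~8.5 degC. The anomaly scale is chosen so that the
    consecutive-day maximum-temperature metric and the heat index straddle
    the published knots (32.95 degC / 79.65) — without that overlap the
    threshold-recovery problem is unidentifiable.
    """

    start: str = "2011-06-01"
    end: str = "2011-08-31"
    station: str = "S1"
    peak_tavg: float = 27.0  # seasonal-curve daily mean at the peak, degC
    annual_amplitude: float = 20.0  # peak-to-trough of the annual cosine, degC
    peak_doy: int = 213  # day of year of the thermal peak (~Aug 1)
    ar_coef: float = 0.7  # AR(1) coefficient of daily anomalies
    innovation_sd: float = 1.8  # anomaly innovation sd, degC
    diurnal_range: float = 8.5  # tmax - tmin, degC
    range_jitter: float = 0.8  # bounded jitter on each half-range, degC
    hum_mean: float = 75.0  # relative humidity mean, %
    hum_sd: float = 13.0
    hum_temp_rho: float = -0.6  # humidity vs temperature-deviation correlation
    precip_prob: float = 0.35  # wet-day probability
    precip_gamma_shape: float = 0.6
    precip_gamma_scale: float = 35.0  # mm
    wind_mean: float = 1.6  # m/s
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")
        for name in ("innovation_sd", "diurnal_range", "range_jitter", "hum_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def dates(self) -> pd.DatetimeIndex:
        d = pd.date_range(self.start, self.end, freq="D")
        if len(d) == 0:
            raise ValueError("empty date range")
        return d


def _seasonal_curve(dates: pd.DatetimeIndex, cfg: WeatherSimConfig) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = 2.0 * np.pi * (doy - cfg.peak_doy) / 365.25
    return cfg.peak_tavg - cfg.annual_amplitude * (1.0 - np.cos(phase)) / 2.0


def simulate_weather(config: WeatherSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one station's daily and hourly weather.

    Returns ``(daily, hourly)`` in the package's CSV dialects: daily has
    ``station, date, tmin, tavg, tmax, rhum, precip, wind, sol_max,
    sol_vol``; hourly has ``station, date, hour, temp`` with a sinusoidal
    cycle through (tmin, tmax) peaking at 15:00. Identical config and seed
    give identical output.
    """
    dates = config.dates()
    n = len(dates)
    rng = np.random.default_rng(config.seed)

    base = _seasonal_curve(dates, config)
    anom = np.zeros(n)
    eps = rng.normal(0.0, config.innovation_sd, size=n)
    for i in range(n):
        anom[i] = (config.ar_coef * anom[i - 1] if i else 0.0) + eps[i]
    tavg = base + anom

    half = config.diurnal_range / 2.0
    j_up = rng.uniform(-config.range_jitter, config.range_jitter, size=n)
    j_dn = rng.uniform(-config.range_jitter, config.range_jitter, size=n)
    # jitter bounded below the half-range so tmin <= tavg <= tmax always
    j_up = np.clip(j_up, -0.9 * half if half > 0 else 0.0, None)
    j_dn = np.clip(j_dn, -0.9 * half if half > 0 else 0.0, None)
    tmax = tavg + half + j_up
    tmin = tavg - half - j_dn

    # humidity anticorrelates with the total temperature deviation (hot
    # spells are dry, sunny spells), not just the AR anomaly
    anom_sd = config.innovation_sd / np.sqrt(1.0 - config.ar_coef**2)
    dev = tavg - float(np.mean(base))
    dev_sd = float(np.sqrt(np.var(base) + anom_sd**2)) if anom_sd > 0 else float(
        np.std(base)
    )
    z = dev / dev_sd if dev_sd > 0 else np.zeros(n)
    rho = config.hum_temp_rho
    hum_noise = rng.normal(0.0, 1.0, size=n)
    rhum = config.hum_mean + config.hum_sd * (
        rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * hum_noise
    )
    rhum = np.clip(rhum, 0.0, 100.0)

    wet = rng.random(n) < config.precip_prob
    precip = np.where(
        wet,
        rng.gamma(config.precip_gamma_shape, config.precip_gamma_scale, size=n),
        0.0,
    )
    wind = rng.gamma(4.0, config.wind_mean / 4.0, size=n)
    # cloudier wet days -> less solar input
    clear = np.clip(1.0 - 0.6 * wet - 0.003 * (rhum - config.hum_mean), 0.05, 1.0)
    sol_max = 3.5 * clear * rng.uniform(0.8, 1.0, size=n)
    sol_vol = 8.0 * sol_max * rng.uniform(0.8, 1.0, size=n) / 2.0

    daily = pd.DataFrame(
        {
            "station": config.station,
            "date": dates,
            "tmin": tmin,
            "tavg": tavg,
            "tmax": tmax,
            "rhum": rhum,
            "precip": precip,
            "wind": wind,
            "sol_max": sol_max,
            "sol_vol": sol_vol,
        }
    )

    hours = np.arange(24)
    # cosine diurnal cycle: minimum at 03:00, maximum at 15:00
    shape = -np.cos(2.0 * np.pi * (hours - 3) / 24.0)  # in [-1, 1]
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    temp = mid[:, None] + amp[:, None] * shape[None, :]
    hourly = pd.DataFrame(
        {
            "station": config.station,
            "date": np.repeat(dates, 24),
            "hour": np.tile(hours, n),
            "temp": temp.ravel(),
        }
    )
    return daily, hourly


def simulate_morbidity(
    features: pd.DataFrame,
    model: MarsModel,
    noise_sd: float,
    seed: int,
    truncate: bool = False,
) -> pd.Series:
    """Standardized morbidity: model prediction + Normal(0, noise_sd) noise.

    With ``truncate`` the draw is floored at zero (rates cannot be
    negative); leave it off when the Gaussian error model itself is under
    test.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mu = np.asarray(model.predict(features), dtype=float)
    rng = np.random.default_rng(seed)
    y = mu + rng.normal(0.0, noise_sd, size=mu.shape) if noise_sd > 0 else mu.copy()
    if truncate:
        y = np.clip(y, 0.0, None)
    return pd.Series(y, index=features.index, name="y_std")


@dataclass
class StudyDesign:
    """Panel dimensions and subgroup mixture of the study emulator.

    Default mixture weights follow the observed composition of the
    surveillance counts (ages ~6/69/25%, ~79% male, ~64% admitted, ~76%
    outdoors). Populations default to county sizes drawn around the
    published mean (303,011, sd 143,257).
    """

    n_centers: int = 74
    n_days: int = 521
    populations: list[int] | None = None
    age_weights: tuple[float, float, float] = (0.059, 0.691, 0.250)
    gender_weights: tuple[float, float] = (0.791, 0.209)
    diagnosis_weights: tuple[float, float] = (0.359, 0.641)  # discharged, admitted
    place_weights: tuple[float, float] = (0.238, 0.762)  # indoors, outdoors
    scale: float = 100_000.0  # standardized outcome = count/population * scale

    def __post_init__(self):
        for name in ("age_weights", "gender_weights", "diagnosis_weights", "place_weights"):
            w = getattr(self, name)
            if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.populations is not None:
            if len(self.populations) != self.n_centers:
                raise ValueError("populations length must equal n_centers")
            if any(p <= 0 for p in self.populations):
                raise ValueError("populations must be positive")


def _default_populations(n: int, rng) -> np.ndarray:
    pops = rng.normal(303_011.0, 143_257.0, size=n)
    return np.maximum(pops, 30_000.0).round().astype(int)


def simulate_study(
    design: StudyDesign,
    weather: list[pd.DataFrame],
    model: MarsModel,
    noise_sd: float,
    seed: int,
    hourly: list[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Emit the center-day study panel.

    ``weather`` holds one daily-weather frame per center (its first
    ``n_days`` + warm-up rows are used; each center keeps its own series).
    Total counts are chosen so the standardized outcome reproduces the
    morbidity draw up to count quantization; subgroup counts are
    multinomial within each subcategory, with the month split
    (June/July vs August) fixed by the calendar date.
    """
    if len(weather) != design.n_centers:
        raise ValueError("need one weather series per center")
    rng = np.random.default_rng(seed)
    pops = (
        np.asarray(design.populations)
        if design.populations is not None
        else _default_populations(design.n_centers, rng)
    )

    rows = []
    for ci in range(design.n_centers):
        h = hourly[ci] if hourly is not None else None
        feats = build_feature_table(weather[ci], h)
        feats = feats.dropna(subset=[v for v in model.variables])
        if len(feats) < design.n_days:
            raise ValueError(
                f"center {ci}: only {len(feats)} usable days < n_days {design.n_days}"
            )
        feats = feats.iloc[: design.n_days].reset_index(drop=True)
        y = simulate_morbidity(
            feats, model, noise_sd, seed=int(rng.integers(2**31)), truncate=True
        )
        pop = int(pops[ci])
        counts = np.rint(y.to_numpy() * pop / design.scale).astype(int)
        counts = np.maximum(counts, 0)
        y_std = counts * design.scale / pop

        age = rng.multinomial(counts, design.age_weights)
        sex = rng.multinomial(counts, design.gender_weights)
        diag = rng.multinomial(counts, design.diagnosis_weights)
        place = rng.multinomial(counts, design.place_weights)
        months = feats["date"].dt.month.to_numpy()
        junjul = np.where(np.isin(months, (6, 7)), counts, 0)

        rows.append(
            pd.DataFrame(
                {
                    "center": f"C{ci + 1:03d}",
                    "date": feats["date"].values,
                    "population": pop,
                    "HWwhole": counts,
                    "HWyoung": age[:, 0],
                    "HWadult": age[:, 1],
                    "HWolder": age[:, 2],
                    "HWmale": sex[:, 0],
                    "HWfemale": sex[:, 1],
                    "HWdisch": diag[:, 0],
                    "HWhospital": diag[:, 1],
                    "HWjunjul": junjul,
                    "HWaug": counts - junjul,
                    "HWin": place[:, 0],
                    "HWout": place[:, 1],
                    "y_std": y_std,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
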