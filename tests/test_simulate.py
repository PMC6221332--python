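import logging

import numpy as np
import pandas as pd
import pytest

import heatthresh as ht
from heatthresh.experiments import summer_covariates
from heatthresh.simulate import (
    SURVEILLANCE_WINDOWS,
    StudyDesign,
    WeatherSimConfig,
    simulate_morbidity,
    simulate_study,
    simulate_weather,
    study_calendar,
)
from heatthresh.weather import build_feature_table

logger = logging.getLogger(__name__)


class TestStudyCalendar:
    def test_one_default_year_is_92_days(self):
        assert len(study_calendar([2011])) == 92

    def test_six_default_years_total_552(self):
        assert len(study_calendar(range(2011, 2017))) == 552

    def test_empty_years(self):
        assert len(study_calendar([])) == 0

    def test_end_before_start_error(self):
        with pytest.raises(ValueError):
            study_calendar([2011], overrides={2011: ("2011-08-01", "2011-07-01")})

    def test_surveillance_window_override(self):
        # 2011 surveillance ran 7/1-9/9; clipped to June-August => 62 days
        cal = study_calendar([2011], overrides=SURVEILLANCE_WINDOWS)
        assert len(cal) == 62
        raw = study_calendar([2011], june_august=False, overrides=SURVEILLANCE_WINDOWS)
        assert len(raw) == 71


class TestSimulateWeather:
    def test_deterministic_curve_without_noise(self):
        cfg = WeatherSimConfig(innovation_sd=0.0, range_jitter=0.0, seed=3)
        daily, _ = simulate_weather(cfg)
        np.testing.assert_allclose(daily["tmax"] - daily["tmin"], cfg.diurnal_range)
        # repeat days differ only via the seasonal curve: smooth, no jumps
        assert daily["tavg"].diff().abs().max() < 0.2

    def test_same_seed_identical(self):
        a, ha = simulate_weather(WeatherSimConfig(seed=9))
        b, hb = simulate_weather(WeatherSimConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ha, hb)

    def test_different_seed_differs(self):
        a, _ = simulate_weather(WeatherSimConfig(seed=1))
        b, _ = simulate_weather(WeatherSimConfig(seed=2))
        assert not a["tavg"].equals(b["tavg"])

    def test_physical_invariants(self):
        daily, hourly = simulate_weather(WeatherSimConfig(seed=4))
        assert (daily["tmin"] <= daily["tavg"]).all()
        assert (daily["tavg"] <= daily["tmax"]).all()
        assert daily["rhum"].between(0, 100).all()
        assert (daily[["precip", "wind", "sol_max", "sol_vol"]] >= 0).all().all()
        assert len(hourly) == 24 * len(daily)

    def test_empty_range_error(self):
        with pytest.raises(ValueError):
            simulate_weather(WeatherSimConfig(start="2011-09-01", end="2011-06-01"))

    def test_long_run_mean_tracks_seasonal_curve(self):
        cfg = WeatherSimConfig(start="2011-06-01", end="2019-08-31", seed=12)
        daily, _ = simulate_weather(cfg)
        anom_sd = cfg.innovation_sd / np.sqrt(1 - cfg.ar_coef**2)
        n = len(daily)
        # AR(1) effective sample size correction for the standard error
        se = anom_sd / np.sqrt(n * (1 - cfg.ar_coef) / (1 + cfg.ar_coef))
        doy = daily["date"].dt.dayofyear.to_numpy(dtype=float)
        curve = cfg.peak_tavg - cfg.annual_amplitude * (
            1 - np.cos(2 * np.pi * (doy - cfg.peak_doy) / 365.25)
        ) / 2
        assert abs((daily["tavg"] - curve).mean()) < 3 * se

    def test_realism_envelope_soft_check(self):
        # study-summary envelopes; logged, only the physically consistent
        # ones asserted
        feats = summer_covariates(5, n=1500)
        frac_tmax = feats["Tmax"].between(16.3, 38.9).mean()
        frac_whum = feats["Whum"].between(28.9, 100.0).mean()
        frac_n1 = feats["Nindex1"].between(56.86, 107.88).mean()
        logger.info(
            "realism envelope: Tmax %.3f Whum %.3f Nindex1 %.3f",
            frac_tmax, frac_whum, frac_n1,
        )
        assert frac_tmax >= 0.99
        assert frac_whum >= 0.99


class TestSimulateMorbidity:
    def test_zero_noise_equals_prediction(self, additive_model):
        feats = summer_covariates(2, n=200)
        y = simulate_morbidity(feats, additive_model, 0.0, seed=1)
        np.testing.assert_allclose(y.to_numpy(), additive_model.predict(feats))

    def test_noise_sd_calibrated(self, additive_model):
        feats = summer_covariates(2, n=5000)
        y = simulate_morbidity(feats, additive_model, 0.05, seed=3)
        resid = y.to_numpy() - additive_model.predict(feats)
        assert abs(resid.std() - 0.05) < 0.05 * 0.05

    def test_same_seed_identical(self, additive_model):
        feats = summer_covariates(2, n=100)
        a = simulate_morbidity(feats, additive_model, 0.02, seed=8)
        b = simulate_morbidity(feats, additive_model, 0.02, seed=8)
        pd.testing.assert_series_equal(a, b)

    def test_truncation_floors_at_zero(self, additive_model):
        feats = summer_covariates(2, n=300)
        y = simulate_morbidity(feats, additive_model, 0.5, seed=5, truncate=True)
        assert (y >= 0).all()

    def test_negative_noise_sd_error(self, additive_model):
        with pytest.raises(ValueError):
            simulate_morbidity(summer_covariates(2, n=50), additive_model, -0.1, seed=0)


def _center_weather(n_centers, n_days, seed0=100):
    out_d, out_h = [], []
    for i in range(n_centers):
        cfg = WeatherSimConfig(
            start="2016-06-01",
            end=str((pd.Timestamp("2016-06-01") + pd.Timedelta(days=n_days + 4)).date()),
            station=f"C{i}",
            seed=seed0 + i,
        )
        d, h = simulate_weather(cfg)
        out_d.append(d)
        out_h.append(h)
    return out_d, out_h


class TestSimulateStudy:
    def test_single_center_single_day(self, additive_model):
        w, h = _center_weather(1, 1)
        panel = simulate_study(
            StudyDesign(n_centers=1, n_days=1), w, additive_model, 0.02, seed=1, hourly=h
        )
        assert len(panel) == 1

    def test_subgroup_additivity(self, additive_model):
        w, h = _center_weather(3, 40)
        panel = simulate_study(
            StudyDesign(n_centers=3, n_days=40), w, additive_model, 0.3, seed=2, hourly=h
        )
        assert (panel["HWmale"] + panel["HWfemale"] == panel["HWwhole"]).all()
        assert (
            panel[["HWyoung", "HWadult", "HWolder"]].sum(axis=1) == panel["HWwhole"]
        ).all()
        assert (panel["HWjunjul"] + panel["HWaug"] == panel["HWwhole"]).all()
        assert (panel["HWdisch"] + panel["HWhospital"] == panel["HWwhole"]).all()

    def test_standardized_outcome_consistent_with_counts(self, additive_model):
        w, h = _center_weather(2, 30)
        design = StudyDesign(n_centers=2, n_days=30)
        panel = simulate_study(design, w, additive_model, 0.3, seed=3, hourly=h)
        np.testing.assert_allclose(
            panel["y_std"],
            panel["HWwhole"] * design.scale / panel["population"],
        )
        assert (panel["y_std"] >= 0).all()

    def test_month_split_follows_calendar(self, additive_model):
        w, h = _center_weather(1, 70)
        panel = simulate_study(
            StudyDesign(n_centers=1, n_days=70), w, additive_model, 0.5, seed=4, hourly=h
        )
        months = pd.to_datetime(panel["date"]).dt.month
        assert (panel.loc[months.isin([6, 7]), "HWaug"] == 0).all()
        assert (panel.loc[months == 8, "HWjunjul"] == 0).all()

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(age_weights=(0.5, 0.5, 0.5))

    def test_weather_count_mismatch_error(self, additive_model):
        w, h = _center_weather(2, 10)
        with pytest.raises(ValueError):
            simulate_study(StudyDesign(n_centers=3, n_days=10), w, additive_model, 0.1, seed=1)

    def test_same_seed_identical_panel(self, additive_model):
        w, h = _center_weather(2, 20)
        d = StudyDesign(n_centers=2, n_days=20)
        a = simulate_study(d, w, additive_model, 0.2, seed=7, hourly=h)
        b = simulate_study(d, w, additive_model, 0.2, seed=7, hourly=h)
        pd.testing.assert_frame_equal(a, b)


class TestEndToEndRecovery:
    def test_pipeline_recovers_published_knots_single_seed(self, additive_model):
        # weather -> features -> morbidity -> fit -> thresholds, one seed;
        # the 20-seed median check lives in the acceptance suite
        feats = summer_covariates(31, n=3000)
        rng = np.random.default_rng(32)
        X = feats[["AvgTmaxLag1", "Nindex1"]].copy()
        y = additive_model.predict(feats) + rng.normal(0, 0.02, len(X))
        res = ht.MarsRegression(y, X).fit()
        thr = res.thresholds().as_dict()
        assert abs(thr["AvgTmaxLag1"] - 32.95) < 0.5
        assert abs(thr["Nindex1"] - 79.65) < 1.0
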