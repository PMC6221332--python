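"""End-to-end orchestration: simulate -> features -> fit -> thresholds -> calendar.

A run is configured by one YAML document with per-stage sections and is
fully reproducible: every artifact is a deterministic function of (config,
seed), and the JSON run report carries the config hash and seed. Partial
outputs of a failing stage are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .mars import FitConfig, MarsRegression, load_model, load_published_model, save_model
from .simulate import (
    StudyDesign,
    WeatherSimConfig,
    simulate_morbidity,
    simulate_study,
    simulate_weather,
)
from .thresholds import default_rules, evaluate_criteria, extract_thresholds, load_rules
from .weather import build_feature_table

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate-weather", "simulate-study", "features", "fit", "thresholds", "calendar"]


@dataclass
class RunConfig:
    """One-file configuration of a pipeline run."""

    seed: int = 0
    out_dir: str = "out"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    weather: dict = field(default_factory=dict)  # WeatherSimConfig fields
    study: dict = field(default_factory=dict)  # StudyDesign fields + noise_sd/model
    fit: dict = field(default_factory=dict)  # FitConfig fields + outcome spec
    rules: str | None = None  # YAML rules path; None -> packaged defaults
    summer_only: bool = True  # restrict fit/calendar stages to June-August
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        payload = {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
        }
        return json.dumps(payload, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _resolve_model(ref, out_dir: Path):
    if ref in (None, "additive", "interaction"):
        return load_published_model(ref or "additive")
    return load_model(str(ref))


def _fit_features(cfg_fit: dict) -> list[str]:
    return list(
        cfg_fit.get("features", ["AvgTmaxLag1", "Nindex1", "Tavg", "Tmax", "Whum"])
    )


def run(config: RunConfig) -> dict:
    """Execute the requested stages; return (and write) the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    for s in config.stages:
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage {s!r}")
    stages = [s for s in STAGE_ORDER if s in config.stages]

    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": stages,
        "artifacts": {},
    }
    paths = {
        "weather": out_dir / "weather.csv",
        "hourly": out_dir / "hourly.csv",
        "features": out_dir / "features.csv",
        "panel": out_dir / "panel.csv",
        "model": out_dir / "model.json",
        "calendar": out_dir / "calendar.csv",
        "yearly": out_dir / "yearly_counts.csv",
        "report": out_dir / "report.json",
    }

    def _require(stage: str, key: str) -> Path:
        p = paths[key]
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r}: missing dependency {p.name} "
                f"(run its producing stage first)"
            )
        return p

    for stage in stages:
        written: list[Path] = []
        try:
            if stage == "simulate-weather":
                wcfg = WeatherSimConfig(**{"seed": config.seed, **config.weather})
                daily, hourly = simulate_weather(wcfg)
                hio.write_table(daily, paths["weather"], "weather_daily")
                written.append(paths["weather"])
                hio.write_table(hourly, paths["hourly"], "weather_hourly")
                written.append(paths["hourly"])
            elif stage == "simulate-study":
                scfg = dict(config.study)
                noise_sd = float(scfg.pop("noise_sd", 0.02))
                model = _resolve_model(scfg.pop("model", None), out_dir)
                warmup = int(scfg.pop("warmup_days", 5))
                design = StudyDesign(**scfg)
                weather_list, hourly_list = [], []
                ss = np.random.SeedSequence(config.seed)
                kids = ss.spawn(design.n_centers + 1)
                start = pd.Timestamp(config.weather.get("start", "2011-06-01"))
                end = start + pd.Timedelta(days=design.n_days + warmup - 1)
                for ci in range(design.n_centers):
                    wcfg = WeatherSimConfig(
                        **{
                            **config.weather,
                            "start": str(start.date()),
                            "end": str(end.date()),
                            "station": f"C{ci + 1:03d}",
                            "seed": int(kids[ci].generate_state(1)[0] % 2**31),
                        }
                    )
                    d, h = simulate_weather(wcfg)
                    weather_list.append(d)
                    hourly_list.append(h)
                panel = simulate_study(
                    design,
                    weather_list,
                    model,
                    noise_sd,
                    seed=int(kids[-1].generate_state(1)[0] % 2**31),
                    hourly=hourly_list,
                )
                hio.write_table(panel, paths["panel"], "panel")
                written.append(paths["panel"])
            elif stage == "features":
                wp = _require(stage, "weather")
                daily = hio.read_table(wp, "weather_daily")
                hourly = (
                    hio.read_table(paths["hourly"], "weather_hourly")
                    if paths["hourly"].exists()
                    else None
                )
                feats = build_feature_table(daily, hourly)
                hio.write_table(feats, paths["features"], "features")
                written.append(paths["features"])
            elif stage == "fit":
                fp = _require(stage, "features")
                feats = hio.read_table(fp, "features")
                if config.summer_only:
                    feats = feats[feats["date"].dt.month.isin((6, 7, 8))]
                fcfg_d = dict(config.fit)
                outcome = fcfg_d.pop("outcome", {}) or {}
                feature_cols = _fit_features(fcfg_d)
                fcfg_d.pop("features", None)
                fit_config = FitConfig(**fcfg_d)
                model_gen = _resolve_model(outcome.get("model"), out_dir)
                noise_sd = float(outcome.get("noise_sd", 0.02))
                y = simulate_morbidity(
                    feats.dropna(subset=feature_cols).reset_index(drop=True),
                    model_gen,
                    noise_sd,
                    seed=(config.seed + 1) % 2**31,
                    truncate=False,
                )
                X = feats.dropna(subset=feature_cols).reset_index(drop=True)
                res = MarsRegression(y, X[feature_cols], config=fit_config).fit()
                save_model(res.spline, paths["model"])
                written.append(paths["model"])
                report["fit"] = {
                    "n_obs": res.spline.n_obs,
                    "gcv": res.spline.gcv,
                    "rss": res.spline.rss,
                    "importance": res.importance,
                    "summary": res.summary(),
                }
            elif stage == "thresholds":
                mp = _require(stage, "model")
                model = load_model(str(mp))
                # importance is not serialized; recover ranking from report
                ts = extract_thresholds(model, model_id=mp.name)
                report["thresholds"] = ts.as_dict()
                report["threshold_annotations"] = ts.annotations
            elif stage == "calendar":
                fp = _require(stage, "features")
                feats = hio.read_table(fp, "features")
                if config.summer_only:
                    feats = feats[feats["date"].dt.month.isin((6, 7, 8))]
                rules = load_rules(config.rules) if config.rules else default_rules()
                cal = evaluate_criteria(feats, rules)
                flags = cal.flags.reset_index().rename(columns={"index": "date"})
                flags.columns = ["date", *cal.flags.columns]
                hio.write_table(flags, paths["calendar"], "calendar")
                written.append(paths["calendar"])
                yearly = cal.yearly_counts()
                yearly.index.name = "year"
                yearly.to_csv(paths["yearly"])
                written.append(paths["yearly"])
                report["yearly_counts"] = {
                    str(ix): {c: int(v) for c, v in row.items()}
                    for ix, row in yearly.iterrows()
                }
                report["calendar_missing"] = {
                    k: int(v) for k, v in cal.missing.items()
                }
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        report["artifacts"].update(
            {p.name: str(p) for p in written}
        )

    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    report["artifacts"]["report.json"] = str(paths["report"])
    return report
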