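"""Heatwave thresholds and warning-day calendars.

A fitted hinge-spline morbidity model defines thresholds inductively: the
knot of every first-degree upward hinge with a positive coefficient is a
point where predicted morbidity starts to rise, i.e. a candidate heatwave
cutoff. Those cutoffs (and the operational ones they are compared against)
are then applied to a daily feature table as warning criteria:

* ``consecutive_exceed`` — variable strictly exceeds the cutoff on
  ``run_length`` consecutive days ending today (the Korean operational
  rule: daily maximum temperature > 33 degC on two straight days);
* ``level_exceed`` — variable >= cutoff on the day;
* ``disjunction`` — OR of other rules.

Per-day flags are aggregated into per-year counts against the eligible-day
denominator (92 June-August days per year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .mars import DOWNWARD, UPWARD, MarsModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thresholds from models


@dataclass(frozen=True)
class ThresholdEntry:
    variable: str
    knot: float
    provenance: str = "manual"


@dataclass
class ThresholdSet:
    """Variable -> knot cutoffs plus non-threshold annotations.

    Annotations describe model structure that does not define a rising
    threshold (downward hinges, negative coefficients, interaction terms).
    """

    entries: list[ThresholdEntry] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {e.variable: e.knot for e in self.entries}

    def __len__(self):
        return len(self.entries)


def extract_thresholds(model: MarsModel, model_id: str = "model") -> ThresholdSet:
    """Read heatwave thresholds off a fitted hinge model.

    A variable's threshold is the knot where its additive component
    function turns upward most sharply — the point where predicted
    morbidity starts to rise. Concretely, for each degree-1 knot the slope
    increase equals the sum of the coefficients of the hinges sharing that
    knot (an upward hinge ``c*max(x-t,0)`` raises the slope by c at t; a
    downward hinge ``c*max(t-x,0)`` has slope -c below t, so it too raises
    the slope by c at t). A rise needs both a large slope increase and a
    genuinely rising function beyond the knot, so each candidate knot is
    scored by min(slope increase, outgoing slope) and the highest-scoring
    knot wins. This reduces to "the upward hinge's knot" for cleanly
    structured models but stays robust when a fit encodes one bend as
    several partially cancelling hinges, or prepends a falling-to-flat
    segment. Interaction terms and knots with non-positive score are
    reported as annotations, not thresholds.
    """
    # gather degree-1 hinges by variable
    hinges: dict[str, list] = {}
    notes: list[str] = []
    for t in model.terms:
        if t.degree == 1:
            hinges.setdefault(t.factors[0].variable, []).append(
                (t.factors[0], t.coefficient)
            )
        else:
            notes.append(f"interaction term: {t} (coef {t.coefficient:g})")
    if not model.terms:
        logger.warning("intercept-only model: empty threshold set")

    entries: list[ThresholdEntry] = []
    for var, hs in hinges.items():
        slope_change: dict[float, float] = {}
        for f, c in hs:
            slope_change[f.knot] = slope_change.get(f.knot, 0.0) + c

        def slope_above(t0: float) -> float:
            s = 0.0
            for f, c in hs:
                if f.direction == UPWARD and f.knot <= t0:
                    s += c
                elif f.direction == DOWNWARD and f.knot > t0:
                    s -= c
            return s

        cands = [
            (min(dc, slope_above(k)), k)
            for k, dc in slope_change.items()
            if dc > 0 and slope_above(k) > 0
        ]
        if cands:
            _, knot = max(cands)
            entries.append(ThresholdEntry(var, knot, provenance=model_id))
            for k, d in sorted(slope_change.items()):
                if k != knot:
                    notes.append(
                        f"secondary knot on {var}: {k:g} (slope change {d:+g})"
                    )
        else:
            for k, d in sorted(slope_change.items()):
                notes.append(
                    f"non-rising knot on {var}: {k:g} (slope change {d:+g})"
                )
    return ThresholdSet(entries=entries, annotations=notes)


# ---------------------------------------------------------------------------
# warning criteria


@dataclass
class CriterionRule:
    """One warning criterion over the daily feature table."""

    name: str
    kind: str  # consecutive_exceed | level_exceed | disjunction
    variable: str | None = None
    cutoff: float | None = None
    run_length: int = 1
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        kinds = ("consecutive_exceed", "level_exceed", "disjunction")
        if self.kind not in kinds:
            raise ValueError(f"rule {self.name!r}: kind must be one of {kinds}")
        if self.kind == "disjunction":
            if not self.members:
                raise ValueError(f"disjunction {self.name!r} needs members")
        else:
            if self.variable is None or self.cutoff is None:
                raise ValueError(f"rule {self.name!r} needs variable and cutoff")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


def default_rules() -> list[CriterionRule]:
    """The operational rule and the model-derived alternatives.

    ``kma_existing`` is the Korean warning trigger (Tmax > 33 degC, two
    straight days). The alternatives carry the published all-visitor
    cutoffs: consecutive-day mean maximum temperature >= 32.58 degC, heat
    index >= 79.64, and their disjunction.
    """
    return [
        CriterionRule("kma_existing", "consecutive_exceed", "Tmax", 33.0, run_length=2),
        CriterionRule("alt1_avgtmaxlag1", "level_exceed", "AvgTmaxLag1", 32.58),
        CriterionRule("alt2_nindex1", "level_exceed", "Nindex1", 79.64),
        CriterionRule(
            "alt3_or",
            "disjunction",
            members=["alt1_avgtmaxlag1", "alt2_nindex1"],
        ),
    ]


def load_rules(source) -> list[CriterionRule]:
    """Load rules from a YAML file path or YAML string."""
    if hasattr(source, "read"):
        docs = yaml.safe_load(source)
    else:
        s = str(source)
        if "\n" in s or s.strip().startswith(("-", "[")):
            docs = yaml.safe_load(s)
        else:
            with open(s) as fh:
                docs = yaml.safe_load(fh)
    if not isinstance(docs, list):
        raise ValueError("rules config must be a YAML list")
    rules = []
    for d in docs:
        rules.append(
            CriterionRule(
                name=d["name"],
                kind=d["kind"],
                variable=d.get("variable"),
                cutoff=d.get("cutoff"),
                run_length=int(d.get("run_length", 1)),
                members=list(d.get("members", [])),
            )
        )
    return rules


@dataclass
class WarningCalendar:
    """Per-day criterion flags, with missing-input bookkeeping."""

    flags: pd.DataFrame  # index: DatetimeIndex; columns: rule names; bool
    missing: pd.Series  # per rule: number of days unflagged due to missing input

    def yearly_counts(self) -> pd.DataFrame:
        return count_by_year(self)


def _rule_flags(rule: CriterionRule, features: pd.DataFrame):
    if rule.variable not in features.columns:
        raise ValueError(f"rule {rule.name!r}: unknown variable {rule.variable!r}")
    x = features[rule.variable].astype(float)
    if rule.kind == "level_exceed":
        valid = x.notna()
        flags = (x >= rule.cutoff) & valid
    else:  # consecutive_exceed, strict >
        hit = x > rule.cutoff
        valid = (
            x.notna().rolling(rule.run_length, min_periods=rule.run_length).sum()
            == rule.run_length
        )
        flags = (
            hit.rolling(rule.run_length, min_periods=rule.run_length).sum()
            == rule.run_length
        ) & valid
        # warm-up days (window not yet filled) count as missing input
        valid.iloc[: rule.run_length - 1] = False
    return flags.astype(bool), (~valid.astype(bool)).sum()


def evaluate_criteria(
    features: pd.DataFrame, rules: list[CriterionRule] | None = None
) -> WarningCalendar:
    """Apply warning criteria day by day.

    ``features`` must carry a ``date`` column (or DatetimeIndex) plus every
    variable any rule references. Days with missing inputs are left
    unflagged and tallied per rule in the calendar's missing report.
    Level rules use >= at the cutoff; consecutive rules use strict >.
    """
    rules = rules if rules is not None else default_rules()
    f = features.copy()
    if "date" in f.columns:
        f = f.set_index(pd.to_datetime(f["date"]))
    elif not isinstance(f.index, pd.DatetimeIndex):
        raise ValueError("features need a 'date' column or DatetimeIndex")

    flags: dict[str, pd.Series] = {}
    missing: dict[str, int] = {}
    by_name = {r.name: r for r in rules}
    for r in rules:
        if r.kind == "disjunction":
            continue
        flags[r.name], missing[r.name] = _rule_flags(r, f)
    for r in rules:
        if r.kind != "disjunction":
            continue
        for m in r.members:
            if m not in by_name:
                raise ValueError(f"disjunction {r.name!r}: unknown member {m!r}")
            if m not in flags:
                raise ValueError(
                    f"disjunction {r.name!r}: member {m!r} is itself a disjunction"
                )
        acc = flags[r.members[0]].copy()
        for m in r.members[1:]:
            acc = acc | flags[m]
        flags[r.name] = acc
        missing[r.name] = 0
    out = pd.DataFrame({r.name: flags[r.name] for r in rules})
    return WarningCalendar(flags=out, missing=pd.Series(missing))


def count_by_year(calendar: WarningCalendar) -> pd.DataFrame:
    """Yearly warning-day counts with the eligible-day denominator.

    Rows: years plus a Total row; columns: ``days`` (eligible days that
    year) then one count per criterion.
    """
    fl = calendar.flags
    if len(fl) == 0:
        cols = ["days"] + list(fl.columns)
        return pd.DataFrame([[0] * len(cols)], index=["Total"], columns=cols)
    years = fl.index.year
    tab = fl.groupby(years).sum().astype(int)
    tab.insert(0, "days", pd.Series(1, index=fl.index).groupby(years).sum().astype(int))
    tab.index = tab.index.astype(str)
    tab.loc["Total"] = tab.sum(axis=0)
    return tab
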