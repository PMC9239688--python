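"""Cohort-level clinical statistics.

Kaplan-Meier time-to-progression curves and the Mantel logrank test
(via lifelines), Kruskal-Wallis nonparametric cohort comparisons (via
scipy), drug-exposure summaries, and the relationship between TTP and the
initial resistant fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .model_core import InvalidInputError
from .protocols import SimulationResult

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "km_curve",
    "logrank",
    "kruskal_wallis",
    "exposure_summary",
    "ttp_vs_resistance",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    arm: str
    time_days: float
    event: bool  # True = progressed, False = censored

    def __post_init__(self):
        if not self.time_days > 0:
            raise InvalidInputError("time_days: must be > 0")


@dataclass
class KMEstimate:
    """Product-limit survival curve; median is None when never reached."""

    table: pd.DataFrame  # columns: time, survival
    median: Optional[float]

    def survival_at(self, t: float) -> float:
        tbl = self.table[self.table["time"] <= t]
        return 1.0 if tbl.empty else float(tbl["survival"].iloc[-1])


def _to_arrays(records: Sequence[SurvivalRecord]):
    t = np.array([r.time_days for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


def km_curve(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with median survival time."""
    if not records:
        raise InvalidInputError("records: need at least one survival record")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    table = pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                          "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(table=table, median=median)


def logrank(arm_a: Sequence[SurvivalRecord], arm_b: Sequence[SurvivalRecord]):
    """Two-sample Mantel logrank test -> (chi-square statistic, p-value)."""
    if not arm_a or not arm_b:
        raise InvalidInputError("logrank: both arms must be non-empty")
    ta, ea = _to_arrays(arm_a)
    tb, eb = _to_arrays(arm_b)
    if not (ea.any() or eb.any()):
        raise InvalidInputError("logrank: no events in either arm; statistic undefined")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def kruskal_wallis(*groups):
    """Kruskal-Wallis rank-based H (tie-corrected) -> (H, p)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidInputError("kruskal_wallis: need >=2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def exposure_summary(items, arms: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-arm mean fraction of time on/off drug.

    Accepts SimulationResult objects (uses the executed schedule over the
    simulation horizon) or PatientSeries (time-weighted over the observed
    on-study span).
    """
    rows = []
    for k, item in enumerate(items):
        if isinstance(item, SimulationResult):
            arm = arms[k] if arms is not None else (item.protocol.kind if item.protocol else "run")
            frac = item.fraction_time_on
            pid = "run%d" % k
        else:  # PatientSeries: time on trial runs to (radiographic) progression
            sched = item.therapy_schedule()
            end = sched.end if item.progression_day is None else min(item.progression_day, sched.end)
            if end <= sched.start:
                raise InvalidInputError("exposure: zero-length schedule for %s" % item.patient_id)
            frac = sched.fraction_on(sched.start, end)
            arm = arms[k] if arms is not None else item.cohort
            pid = item.patient_id
        rows.append({"patient_id": pid, "arm": arm, "fraction_on": frac})
    df = pd.DataFrame(rows)
    out = df.groupby("arm", sort=True)["fraction_on"].agg(["mean", "count"]).reset_index()
    out = out.rename(columns={"mean": "mean_fraction_on", "count": "n"})
    out["mean_fraction_off"] = 1.0 - out["mean_fraction_on"]
    return out


def ttp_vs_resistance(table: pd.DataFrame):
    """Per-arm regression of TTP on initial resistant fraction.

    ``table`` columns: resistant_fraction, ttp_days, arm.  Returns a dict
    with per-arm (slope, intercept, r, p) and a cross-arm separation check:
    the number of adaptive-arm patients lying below the continuous-arm
    regression line (zero when adaptive therapy dominates at every level of
    pretreatment resistance).
    """
    out = {"arms": {}}
    for arm, grp in table.groupby("arm"):
        if len(grp) < 3:
            raise InvalidInputError("ttp_vs_resistance: need >=3 patients per arm")
        x = grp["resistant_fraction"].to_numpy(dtype=float)
        y = grp["ttp_days"].to_numpy(dtype=float)
        if np.all(x == x[0]):
            raise InvalidInputError("ttp_vs_resistance: degenerate resistant fractions in arm %r" % arm)
        res = stats.linregress(x, y)
        out["arms"][arm] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r": float(res.rvalue),
            "p": float(res.pvalue),
            "n": int(len(grp)),
        }
    if {"adaptive", "continuous"} <= set(out["arms"]):
        cont = out["arms"]["continuous"]
        ad = table[table["arm"] == "adaptive"]
        pred = cont["slope"] * ad["resistant_fraction"].to_numpy() + cont["intercept"]
        out["adaptive_below_continuous_line"] = int(np.sum(ad["ttp_days"].to_numpy() < pred))
    return out
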