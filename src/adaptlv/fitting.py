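"""Two-step mapping from longitudinal PSA series to model parameters.

Step 1: per-patient log-linear slopes.  The pre-therapy rise of PSA
estimates the sensitive growth rate r_S (resistant cells are assumed a
negligible fraction before treatment); the post-progression rise in the
continuous-therapy arm estimates the resistant rate r_R (the population is
assumed predominantly resistant after progression).  Patient-specific
slopes are pooled by arithmetic mean into patient-wide rates.

Step 2: with (r_S, r_R) fixed, a nested constrained least-squares fit.  The
outer search walks a coarse logarithmic grid over the patient-wide pair
(beta_SC, alpha_RS), refines the grid locally around the coarse minimum and
finishes with a deterministic simplex polish; for every outer candidate an
inner derivative-free fit estimates each patient's initial subpopulations
(x_S(0), x_R(0)) by minimising the squared difference between model PSA and
observed PSA on that patient's observation days.  The cohort objective is
the sum over patients.  alpha_SR is fixed at 1, so any cost of resistance
appears as alpha_RS > 1.

Observed PSA maps to cell units through one global conversion constant
(absolute population sizes are identified only up to this scale).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kernels
from .model_core import DEFAULT_CONVERSION, InvalidInputError, LVParams, default_params
from .protocols import Protocol, ProgressionRule, SimulationResult, TreatmentSchedule, run_protocol

__all__ = [
    "PatientSeries",
    "GrowthRateEstimate",
    "CohortFit",
    "estimate_sensitive_rate",
    "estimate_resistant_rate",
    "pool_rates",
    "compare_rate_sets",
    "fit_cohort",
    "retrospective_protocol_swap",
    "read_patient_csv",
    "read_trial_xlsx",
]


class InsufficientDataError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class PatientSeries:
    """One patient's observed PSA record with therapy annotations.

    ``observations`` has columns day, psa, on_therapy; a therapy flag at day
    d is taken to hold on [d, next observation day).  Days before 0 are the
    pre-therapy monitoring segment.
    """

    patient_id: str
    cohort: str
    observations: pd.DataFrame
    baseline_psa: float
    progression_day: Optional[float] = None

    def __post_init__(self):
        obs = self.observations.reset_index(drop=True)
        days = obs["day"].to_numpy(dtype=float)
        psa = obs["psa"].to_numpy(dtype=float)
        if np.any(np.diff(days) <= 0):
            raise InvalidInputError("observations: days must be strictly increasing")
        if np.any(psa <= 0) or not np.all(np.isfinite(psa)):
            raise InvalidInputError("observations: psa must be finite and > 0")
        if not self.baseline_psa > 0:
            raise InvalidInputError("baseline_psa: must be > 0")
        self.observations = obs

    # -- segment views --------------------------------------------------
    @property
    def first_on_day(self) -> Optional[float]:
        on = self.observations[self.observations["on_therapy"].astype(bool)]
        return None if on.empty else float(on["day"].iloc[0])

    def pre_therapy(self) -> pd.DataFrame:
        """Observations at or before first abiraterone exposure."""
        f = self.first_on_day
        obs = self.observations
        return obs if f is None else obs[obs["day"] <= f]

    def on_study(self) -> pd.DataFrame:
        return self.observations[self.observations["day"] >= 0]

    def post_progression(self) -> pd.DataFrame:
        if self.progression_day is None:
            return self.observations.iloc[0:0]
        return self.observations[self.observations["day"] > self.progression_day]

    def therapy_schedule(self, end: Optional[float] = None) -> TreatmentSchedule:
        """Reconstruct the on/off schedule from the dosing annotations."""
        obs = self.on_study()
        days = obs["day"].to_numpy(dtype=float)
        flags = obs["on_therapy"].astype(bool).to_numpy()
        if days.size == 0:
            raise InsufficientDataError("patient %s: no on-study observations" % self.patient_id)
        end = float(days[-1]) if end is None else end
        intervals = []
        for k in range(days.size):
            a = days[k]
            b = days[k + 1] if k + 1 < days.size else max(end, days[-1])
            if b > a:
                intervals.append((a, b, bool(flags[k])))
        if not intervals:
            intervals = [(days[0], days[0] + 1.0, bool(flags[0]))]
        return TreatmentSchedule(intervals)


@dataclass
class GrowthRateEstimate:
    patient_id: str
    rate: float
    stderr: float
    n_points: int
    day_range: tuple
    note: str = ""


def _loglinear(days: np.ndarray, psa: np.ndarray):
    res = stats.linregress(days, np.log(psa))
    return float(res.slope), float(res.stderr) if np.isfinite(res.stderr) else 0.0


def estimate_sensitive_rate(series: PatientSeries, min_points: int = 3) -> GrowthRateEstimate:
    """Sensitive growth rate from the initial rise of PSA before therapy.

    Uses the earliest contiguous non-decreasing run of at least
    ``min_points`` pre-therapy observations; falls back to all pre-therapy
    points (noted in diagnostics) when no clean rising run exists.
    """
    pre = series.pre_therapy()
    days = pre["day"].to_numpy(dtype=float)
    psa = pre["psa"].to_numpy(dtype=float)
    if days.size < min_points:
        raise InsufficientDataError(
            "patient %s: %d pre-therapy points (< %d)" % (series.patient_id, days.size, min_points)
        )
    note = ""
    run_start, best = 0, None
    k = 0
    while k < days.size:
        j = k
        while j + 1 < days.size and psa[j + 1] >= psa[j]:
            j += 1
        if j - k + 1 >= min_points:
            best = (k, j)
            break
        k = j + 1
    if best is None:
        best = (0, days.size - 1)
        note = "no rising run; used all pre-therapy points"
    a, b = best
    slope, se = _loglinear(days[a : b + 1], psa[a : b + 1])
    return GrowthRateEstimate(
        patient_id=series.patient_id,
        rate=slope,
        stderr=se,
        n_points=b - a + 1,
        day_range=(float(days[a]), float(days[b])),
        note=note,
    )


def estimate_resistant_rate(
    series: PatientSeries, progression_day: Optional[float] = None, min_points: int = 3
) -> GrowthRateEstimate:
    """Resistant growth rate from the PSA rise after disease progression."""
    day = series.progression_day if progression_day is None else progression_day
    if day is None:
        raise InsufficientDataError("patient %s: no progression day recorded" % series.patient_id)
    post = series.observations[series.observations["day"] > day]
    days = post["day"].to_numpy(dtype=float)
    psa = post["psa"].to_numpy(dtype=float)
    if days.size < min_points:
        raise InsufficientDataError(
            "patient %s: %d post-progression points (< %d)" % (series.patient_id, days.size, min_points)
        )
    slope, se = _loglinear(days, psa)
    return GrowthRateEstimate(
        patient_id=series.patient_id,
        rate=slope,
        stderr=se,
        n_points=days.size,
        day_range=(float(days[0]), float(days[-1])),
        note="declining series" if slope < 0 else "",
    )


def pool_rates(estimates: Sequence[GrowthRateEstimate]) -> float:
    """Patient-wide rate = arithmetic mean of the patient-specific estimates."""
    if not estimates:
        raise InsufficientDataError("no growth-rate estimates to pool")
    return float(np.mean([e.rate for e in estimates]))


def compare_rate_sets(a: Sequence[GrowthRateEstimate], b: Sequence[GrowthRateEstimate]):
    """Nonparametric (Kruskal-Wallis) comparison of two rate sets -> (H, p)."""
    stat, p = stats.kruskal([e.rate for e in a], [e.rate for e in b])
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Step 2: nested cohort fit
# ---------------------------------------------------------------------------


@dataclass
class _PatientData:
    patient_id: str
    cohort: str
    days: np.ndarray
    psa: np.ndarray
    seg_starts: np.ndarray
    seg_on: np.ndarray


def _prepare_patient(series: PatientSeries, min_obs: int) -> Optional[_PatientData]:
    obs = series.on_study()
    if series.cohort == "continuous" and series.progression_day is not None:
        obs = obs[obs["day"] <= series.progression_day]
    days = obs["day"].to_numpy(dtype=float)
    psa = obs["psa"].to_numpy(dtype=float)
    if days.size < min_obs:
        warnings.warn(
            "patient %s excluded from fit: %d on-study observations (< %d)"
            % (series.patient_id, days.size, min_obs)
        )
        return None
    flags = obs["on_therapy"].astype(bool).to_numpy()
    change = np.nonzero(flags[1:] != flags[:-1])[0] + 1
    seg_starts = np.concatenate(([days[0]], days[change]))
    seg_on = np.concatenate(([flags[0]], flags[change])).astype(np.int64)
    return _PatientData(series.patient_id, series.cohort, days, psa, seg_starts, seg_on)


def _model_psa(pd_: _PatientData, r, K_arr, alpha_m, drop, beta, x0, conversion, h_max):
    states = _kernels.sim_at_times(
        x0, pd_.seg_starts, pd_.seg_on, pd_.days, h_max, r, K_arr, alpha_m, drop, beta
    )
    return states.sum(axis=1) / conversion


def _inner_fit(pd_, r, K_arr, alpha_m, drop, beta, conversion, K, h_max, weight, starts, maxfev):
    """Constrained fit of one patient's (x_S0, x_R0), parameterised as
    (total, resistant fraction); deterministic multistart Nelder-Mead."""
    wnorm = pd_.psa.size if weight == "patient" else 1.0

    def objective(p):
        total, f = p
        x0 = np.array([total * (1.0 - f), total * f])
        model = _model_psa(pd_, r, K_arr, alpha_m, drop, beta, x0, conversion, h_max)
        return float(np.sum((model - pd_.psa) ** 2)) / wnorm

    bounds = [(K * 1e-3, K * 0.999), (0.0, 1.0)]
    best = None
    for p0 in starts:
        res = optimize.minimize(
            objective,
            np.asarray(p0, dtype=float),
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": maxfev, "xatol": 0.5, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    total, f = best.x
    return float(total), float(f), float(best.fun)


_DEFAULT_STARTS = ((2500.0, 0.05), (2500.0, 0.5), (8000.0, 0.05), (8000.0, 0.5))


@dataclass
class CohortFit:
    """Cohort-wide fitted parameters, per-patient states and diagnostics."""

    r_s: float
    r_r: float
    beta_sc: float
    alpha_rs: float
    objective: float
    per_patient: pd.DataFrame
    surface: pd.DataFrame
    flat_directions: list
    conversion: float
    K: float
    treatment_drop: float
    excluded: list = field(default_factory=list)

    def params(self) -> LVParams:
        return default_params(
            r_s=self.r_s, r_r=self.r_r, beta_sc=self.beta_sc,
            alpha_rs=self.alpha_rs, K=self.K, drop=self.treatment_drop,
        )

    def to_json(self, path):
        payload = {
            "r_s": self.r_s,
            "r_r": self.r_r,
            "beta_sc": self.beta_sc,
            "alpha_rs": self.alpha_rs,
            "objective": self.objective,
            "conversion": self.conversion,
            "K": self.K,
            "treatment_drop": self.treatment_drop,
            "flat_directions": self.flat_directions,
            "excluded": self.excluded,
            "per_patient": self.per_patient.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_cohort(
    patients: Sequence[PatientSeries],
    r_s: float,
    r_r: float,
    K: float = 10_000.0,
    conversion: float = DEFAULT_CONVERSION,
    beta_bounds: tuple = (1.0, 20.0),
    alpha_bounds: tuple = (0.5, 12.0),
    n_coarse: int = 7,
    n_refine: int = 5,
    polish: bool = True,
    treatment_drop: float = 0.9,
    weight: str = "observation",
    min_obs: int = 5,
    h_max: float = 0.25,
    inner_maxfev: int = 200,
    polish_maxfev: int = 60,
) -> CohortFit:
    """Nested grid-plus-refinement least-squares fit of (beta_SC, alpha_RS).

    Post-progression observations of continuous-arm patients are excluded
    (therapy changes at progression, so those points no longer follow the
    abiraterone-modulated model; they feed the step-1 resistant-rate
    estimator instead).  Patients with fewer than ``min_obs`` usable
    observations are dropped with a warning.
    """
    if weight not in ("observation", "patient"):
        raise InvalidInputError("weight: choose 'observation' or 'patient'")
    prepared, excluded = [], []
    for s in patients:
        fd = _prepare_patient(s, min_obs)
        if fd is None:
            excluded.append(s.patient_id)
        else:
            prepared.append(fd)
    if not prepared:
        raise FitError("no patient has enough usable observations to fit")

    r = np.array([r_s, r_r], dtype=float)
    K_arr = np.array([K, K], dtype=float)
    drop = np.array([treatment_drop, 0.0], dtype=float)
    warm: dict = {}
    surface_rows: list = []

    def cohort_objective(beta, alpha, stage, maxfev=inner_maxfev):
        alpha_m = np.array([[1.0, 1.0], [alpha, 1.0]])
        total_obj = 0.0
        fits = {}
        for fd in prepared:
            if fd.patient_id in warm and stage in ("refine", "polish"):
                # local outer moves: warm start plus two spread starts suffice
                starts = [warm[fd.patient_id], _DEFAULT_STARTS[0], _DEFAULT_STARTS[3]]
            else:
                starts = list(_DEFAULT_STARTS)
                if fd.patient_id in warm:
                    starts.append(warm[fd.patient_id])
            total, f, sse = _inner_fit(
                fd, r, K_arr, alpha_m, drop, beta, conversion, K, h_max, weight, starts, maxfev
            )
            warm[fd.patient_id] = (total, f)
            fits[fd.patient_id] = (total, f, sse)
            total_obj += sse
        surface_rows.append({"beta_sc": beta, "alpha_rs": alpha, "objective": total_obj, "stage": stage})
        return total_obj, fits

    beta_coarse = np.geomspace(*beta_bounds, n_coarse)
    alpha_coarse = np.geomspace(*alpha_bounds, n_coarse)
    coarse = np.empty((n_coarse, n_coarse))
    for i, b in enumerate(beta_coarse):
        for j, a in enumerate(alpha_coarse):
            coarse[i, j], _ = cohort_objective(b, a, "coarse")
    bi, aj = np.unravel_index(np.argmin(coarse), coarse.shape)

    beta_ref = np.geomspace(beta_coarse[max(bi - 1, 0)], beta_coarse[min(bi + 1, n_coarse - 1)], n_refine)
    alpha_ref = np.geomspace(alpha_coarse[max(aj - 1, 0)], alpha_coarse[min(aj + 1, n_coarse - 1)], n_refine)
    best = (coarse[bi, aj], beta_coarse[bi], alpha_coarse[aj])
    for b in beta_ref:
        for a in alpha_ref:
            val, _ = cohort_objective(b, a, "refine")
            if val < best[0]:
                best = (val, b, a)

    if polish:
        lb = np.log([beta_bounds[0], alpha_bounds[0]])
        ub = np.log([beta_bounds[1], alpha_bounds[1]])

        def polish_obj(logp):
            b, a = np.exp(logp)
            val, _ = cohort_objective(b, a, "polish")
            return val

        res = optimize.minimize(
            polish_obj,
            np.log([best[1], best[2]]),
            method="Nelder-Mead",
            bounds=list(zip(lb, ub)),
            options={"maxfev": polish_maxfev, "xatol": 1e-4, "fatol": 1e-12},
        )
        b, a = np.exp(res.x)
        if res.fun < best[0]:
            best = (res.fun, float(b), float(a))

    # flat-direction guard: a parameter absent from the dynamics (e.g.
    # alpha_RS in a cohort with no resistant cells) leaves the objective
    # constant along its axis; probe the bounds at the minimizer and compare
    # the spread with the overall objective scale
    flat = []
    scale = 1e-6 * (1.0 + float(np.max(coarse) - np.min(coarse)))
    probes_a = [cohort_objective(best[1], a, "probe")[0] for a in alpha_bounds]
    if max(probes_a + [best[0]]) - min(probes_a + [best[0]]) <= scale:
        flat.append("alpha_rs")
    probes_b = [cohort_objective(b, best[2], "probe")[0] for b in beta_bounds]
    if max(probes_b + [best[0]]) - min(probes_b + [best[0]]) <= scale:
        flat.append("beta_sc")

    final_obj, fits = cohort_objective(best[1], best[2], "final", maxfev=2 * inner_maxfev)
    if final_obj > best[0]:
        final_obj = best[0]

    rows = []
    for fd in prepared:
        total, f, sse = fits[fd.patient_id]
        rows.append(
            {
                "patient_id": fd.patient_id,
                "cohort": fd.cohort,
                "x_s0": total * (1.0 - f),
                "x_r0": total * f,
                "total0": total,
                "resistant_fraction": f,
                "sse": sse,
                "n_obs": int(fd.days.size),
            }
        )
    per_patient = pd.DataFrame(rows)
    assert np.all(per_patient["x_s0"] >= 0) and np.all(per_patient["x_r0"] >= 0)
    assert np.all(per_patient["x_s0"] + per_patient["x_r0"] <= K)

    return CohortFit(
        r_s=float(r_s),
        r_r=float(r_r),
        beta_sc=float(best[1]),
        alpha_rs=float(best[2]),
        objective=float(final_obj),
        per_patient=per_patient,
        surface=pd.DataFrame(surface_rows),
        flat_directions=flat,
        conversion=conversion,
        K=K,
        treatment_drop=treatment_drop,
        excluded=excluded,
    )


def retrospective_protocol_swap(
    fit: CohortFit,
    patient_id: str,
    counterfactual: Protocol,
    horizon_days: float = 1800.0,
    rule: Optional[ProgressionRule] = None,
) -> SimulationResult:
    """Re-simulate a fitted virtual patient under a counterfactual protocol."""
    row = fit.per_patient[fit.per_patient["patient_id"] == patient_id]
    if row.empty:
        raise KeyError("patient %r not present in fit" % patient_id)
    x0 = np.array([row["x_s0"].iloc[0], row["x_r0"].iloc[0]])
    return run_protocol(fit.params(), x0, counterfactual, horizon_days,
                        conversion=fit.conversion, rule=rule)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_COLUMNS = ("patient_id", "cohort", "day", "psa", "on_therapy")


def _series_from_frame(df: pd.DataFrame) -> list:
    for col in _COLUMNS:
        if col not in df.columns:
            raise InvalidInputError("input table: missing column %r" % col)
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        prog = None
        if "progression_day" in grp.columns:
            vals = pd.to_numeric(grp["progression_day"], errors="coerce").dropna()
            if not vals.empty:
                prog = float(vals.iloc[0])
        if "baseline_psa" in grp.columns and pd.notna(grp["baseline_psa"].iloc[0]):
            baseline = float(grp["baseline_psa"].iloc[0])
        else:
            at0 = grp[grp["day"] == 0]
            baseline = float(at0["psa"].iloc[0]) if not at0.empty else float(grp["psa"].iloc[0])
        out.append(
            PatientSeries(
                patient_id=str(pid),
                cohort=str(grp["cohort"].iloc[0]),
                observations=grp[["day", "psa", "on_therapy"]].astype(
                    {"day": float, "psa": float}
                ),
                baseline_psa=baseline,
                progression_day=prog,
            )
        )
    return out


def read_patient_csv(path) -> list:
    """Read the cohort CSV schema into PatientSeries objects."""
    return _series_from_frame(pd.read_csv(path))


def read_trial_xlsx(path, sheet_name=0, column_map: Optional[dict] = None) -> list:
    """Thin reader for an XLSX sheet in the deposited-trial layout.

    Column names are lower-cased and stripped; ``column_map`` renames any
    remaining nonstandard headers onto the CSV schema.
    """
    df = pd.read_excel(path, sheet_name=sheet_name)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    if column_map:
        df = df.rename(columns=column_map)
    return _series_from_frame(df)
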