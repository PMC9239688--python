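"""Virtual two-arm cohorts with the statistical structure the analysis assumes.

Each virtual patient is simulated from the true competition model under the
arm's protocol (adaptive therapy executed at discrete monitoring visits, or
continuous dosing), then observed: PSA is sampled at the visit cadence with
multiplicative lognormal noise, therapy flags are annotated as the protocol
actually executed them, and a progression day is exported for
continuous-arm patients.

The emitted record deliberately mirrors the structure of real trial data
rather than being one seamless ODE solution:

* the pre-therapy monitoring segment (days < 0) rises log-linearly at the
  patient's sensitive growth rate -- the regime the step-1 r_S estimator
  assumes (resistant cells negligible, burden far from carrying capacity);
* on-study observations come from the full model under the executed
  schedule;
* post-progression observations (continuous arm, therapy changed) rise
  log-linearly at the patient's resistant rate, feeding the step-1 r_R
  estimator; they are excluded from the step-2 fit.

Hidden ground truth (initial subpopulations, true TTP, eligibility) is
returned separately so recovery tests never peek through the data stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fitting import PatientSeries
from .model_core import DEFAULT_CONVERSION, LVParams, default_params
from .protocols import Protocol, ProgressionRule, run_protocol

__all__ = ["CohortSpec", "CohortBundle", "generate_patient", "generate_cohort", "exponential_series"]

_ARM_CODE = {"adaptive": 1, "continuous": 2}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a virtual cohort (the defaults are the trial's)."""

    n_adaptive: int = 17
    n_continuous: int = 16
    r_s: float = 0.0156  # sensitive growth rate, /day
    r_r: float = 0.0091  # resistant growth rate, /day
    beta_sc: float = 8.0
    alpha_rs: float = 6.0
    alpha_sr: float = 1.0
    K: float = 10_000.0
    treatment_drop: float = 0.9
    conversion: float = DEFAULT_CONVERSION  # cells per ng/ml
    resistant_fraction_range: tuple = (0.01, 0.4)
    baseline_psa_median: float = 25.0  # ng/ml; median maps to K/2
    baseline_psa_sigma: float = 0.45  # lognormal sigma
    burden_frac_bounds: tuple = (0.15, 0.75)  # accepted initial burden as fraction of K
    visit_interval_range: tuple = (28, 42)  # days between PSA draws
    noise_sigma: float = 0.1  # sd of log multiplicative PSA noise
    rate_jitter_sigma: float = 0.1  # per-patient lognormal jitter on segment rates
    pre_therapy_visits: int = 4
    pre_therapy_interval: float = 28.0
    post_progression_visits: int = 4
    #: days between the PSA-based surrogate progression and its radiographic
    #: confirmation (the trial imaged every 12 weeks); patients stay on study,
    #: and on therapy, until the confirmed date.
    radiographic_lag_days: float = 84.0
    stop_fraction: float = 0.5
    restart_fraction: float = 1.0
    withdrawal_delay_days: float = 0.0
    restart_delay_days: float = 0.0
    #: execution mode of the adaptive arm: "adaptive_sampled" switches only at
    #: monitoring visits (the trial's operating reality), "adaptive_ideal"
    #: switches at exact threshold crossings (the idealised protocol).
    adaptive_kind: str = "adaptive_sampled"
    horizon_days: float = 1800.0
    seed: int = 0

    def params(self) -> LVParams:
        return default_params(
            r_s=self.r_s, r_r=self.r_r, beta_sc=self.beta_sc, alpha_rs=self.alpha_rs,
            alpha_sr=self.alpha_sr, K=self.K, drop=self.treatment_drop,
        )

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _patient_rng(spec: CohortSpec, arm: str, index: int) -> np.random.Generator:
    # counter-based substream: stable under insertion/removal of other patients
    return np.random.default_rng(np.random.SeedSequence((spec.seed, _ARM_CODE[arm], index)))


def _draw_baseline(spec: CohortSpec, rng) -> float:
    """Baseline PSA (ng/ml) whose implied burden lies in the model's dynamic range."""
    lo = spec.burden_frac_bounds[0] * spec.K / spec.conversion
    hi = spec.burden_frac_bounds[1] * spec.K / spec.conversion
    for _ in range(1000):
        psa = spec.baseline_psa_median * np.exp(rng.normal(0.0, spec.baseline_psa_sigma))
        if lo <= psa <= hi:
            return float(psa)
    return float(np.clip(psa, lo, hi))  # pragma: no cover


def generate_patient(spec: CohortSpec, arm: str, index: int):
    """One virtual patient -> (PatientSeries, ground-truth dict)."""
    if arm not in _ARM_CODE:
        raise ValueError("arm must be 'adaptive' or 'continuous'")
    rng = _patient_rng(spec, arm, index)
    params = spec.params()

    baseline_psa = _draw_baseline(spec, rng)
    total0 = baseline_psa * spec.conversion
    fraction = rng.uniform(*spec.resistant_fraction_range)
    x0 = np.array([total0 * (1.0 - fraction), total0 * fraction])
    r_s_i = spec.r_s * np.exp(rng.normal(0.0, spec.rate_jitter_sigma))
    r_r_i = spec.r_r * np.exp(rng.normal(0.0, spec.rate_jitter_sigma))

    # monitoring visits (integer days, trial cadence 4-6 weeks)
    lo, hi = spec.visit_interval_range
    visits = [0.0]
    while visits[-1] < spec.horizon_days:
        visits.append(visits[-1] + float(rng.integers(lo, hi + 1)))
    visits = np.array(visits[:-1]) if visits[-1] > spec.horizon_days else np.array(visits)

    if arm == "adaptive":
        protocol = Protocol(
            kind=spec.adaptive_kind,
            stop_fraction=spec.stop_fraction,
            restart_fraction=spec.restart_fraction,
            withdrawal_delay_days=spec.withdrawal_delay_days,
            restart_delay_days=spec.restart_delay_days,
        )
        sim = run_protocol(
            params, x0, protocol, spec.horizon_days, conversion=spec.conversion,
            observation_times=visits if spec.adaptive_kind == "adaptive_sampled" else None,
        )
    else:
        sim = run_protocol(
            params, x0, Protocol(kind="continuous"), spec.horizon_days, conversion=spec.conversion
        )

    # eligibility: >=50% PSA decline within two months of starting therapy
    early = sim.trajectory.times <= 60.0
    eligible = bool(
        np.min(sim.trajectory.psa(spec.conversion)[early]) <= 0.5 * baseline_psa * (1 + 1e-6)
    )

    # progression recorded at the first visit on/after radiographic confirmation
    progression_day: Optional[float] = None
    if sim.ttp_days is not None:
        later = visits[visits >= sim.ttp_days + spec.radiographic_lag_days]
        progression_day = float(later[0]) if later.size else float(visits[-1])

    rows = []
    noise = lambda: float(np.exp(rng.normal(0.0, spec.noise_sigma))) if spec.noise_sigma > 0 else 1.0
    # pre-therapy rising segment (log-linear at the patient's sensitive rate)
    for k in range(spec.pre_therapy_visits, 0, -1):
        d = -k * spec.pre_therapy_interval
        rows.append((d, baseline_psa * np.exp(r_s_i * d) * noise(), 0))
    # on-study observations from the executed protocol
    end_day = progression_day if progression_day is not None else spec.horizon_days
    for v in visits[visits <= end_day]:
        psa_true = float(sim.trajectory.at(v).sum()) / spec.conversion
        rows.append((float(v), psa_true * noise(), int(sim.schedule.flag_at(float(v)))))
    # post-progression regrowth segment (continuous arm; therapy changed, off-model)
    if arm == "continuous" and progression_day is not None:
        psa_prog = float(sim.trajectory.at(progression_day).sum()) / spec.conversion
        d = progression_day
        for _ in range(spec.post_progression_visits):
            d += float(rng.integers(lo, hi + 1))
            rows.append((d, psa_prog * np.exp(r_r_i * (d - progression_day)) * noise(), 0))

    obs = pd.DataFrame(rows, columns=["day", "psa", "on_therapy"])
    pid = "%s%03d" % ("A" if arm == "adaptive" else "C", index + 1)
    series = PatientSeries(
        patient_id=pid,
        cohort=arm,
        observations=obs,
        baseline_psa=float(obs.loc[obs["day"] == 0, "psa"].iloc[0]),
        progression_day=progression_day,
    )
    truth = {
        "patient_id": pid,
        "cohort": arm,
        "x_s0": float(x0[0]),
        "x_r0": float(x0[1]),
        "total0": float(total0),
        "resistant_fraction": float(fraction),
        "baseline_psa_true": baseline_psa,
        "ttp_days": None if sim.ttp_days is None else float(sim.ttp_days),
        "progression_day": progression_day,
        "n_cycles": int(sim.n_cycles),
        "fraction_time_on": float(sim.fraction_time_on),
        "eligible": eligible,
        "segment_r_s": float(r_s_i),
        "segment_r_r": float(r_r_i),
    }
    return series, truth


@dataclass
class CohortBundle:
    patients: list
    truth: pd.DataFrame
    manifest: dict

    def to_frame(self) -> pd.DataFrame:
        frames = []
        prog_map = dict(zip(self.truth["patient_id"], self.truth["progression_day"]))
        for s in self.patients:
            df = s.observations.copy()
            df.insert(0, "patient_id", s.patient_id)
            df.insert(1, "cohort", s.cohort)
            prog = prog_map.get(s.patient_id)
            df["progression_day"] = [
                prog if (prog is not None and d >= prog) else np.nan for d in df["day"]
            ]
            df["baseline_psa"] = s.baseline_psa
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def generate_cohort(spec: CohortSpec, out_dir=None) -> CohortBundle:
    """Generate the full two-arm cohort; optionally write the file bundle."""
    patients, truths = [], []
    for arm, n in (("adaptive", spec.n_adaptive), ("continuous", spec.n_continuous)):
        for i in range(n):
            s, t = generate_patient(spec, arm, i)
            patients.append(s)
            truths.append(t)
    bundle = CohortBundle(
        patients=patients,
        truth=pd.DataFrame(truths),
        manifest={"seed": spec.seed, "spec_hash": spec.spec_hash(), "spec": asdict(spec)},
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "patients").mkdir(parents=True, exist_ok=True)
        combined = bundle.to_frame()
        combined.to_csv(out / "cohort.csv", index=False)
        for s in bundle.patients:
            combined[combined["patient_id"] == s.patient_id].to_csv(
                out / "patients" / ("%s.csv" % s.patient_id), index=False
            )
        bundle.truth.to_json(out / "ground_truth.json", orient="records", indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, default=str)
    return bundle


def exponential_series(
    psa0: float, rate: float, days, sigma: float = 0.0, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """PSA series from the model's low-burden exponential phase.

    PSA(t) = psa0 * exp(rate * t), optionally with multiplicative lognormal
    noise -- the generating regime the step-1 log-linear estimators assume.
    """
    days = np.asarray(days, dtype=float)
    psa = psa0 * np.exp(rate * days)
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        psa = psa * np.exp(rng.normal(0.0, sigma, size=days.size))
    return pd.DataFrame({"day": days, "psa": psa})
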