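"""Run configuration: YAML defaults, overrides, hashing, pipeline staging."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model_core import LVParams, default_params
from .protocols import Protocol, ProgressionRule
from .synthetic_data import CohortSpec

__all__ = ["RunConfig", "run_pipeline"]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _load_defaults() -> dict:
    with resources.files("adaptlv.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class RunConfig:
    """Nested configuration merged over the shipped defaults file."""

    data: dict = field(default_factory=_load_defaults)

    @classmethod
    def load(cls, path=None, seed: Optional[int] = None) -> "RunConfig":
        data = _load_defaults()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            data = _deep_merge(data, user)
        if seed is not None:
            data.setdefault("cohort", {})["seed"] = int(seed)
        return cls(data=data)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data.get("cohort", {}).get("seed", 0))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    # -- object builders ------------------------------------------------
    def model_params(self) -> LVParams:
        m = self.data["model"]
        return default_params(
            r_s=m["r_s"], r_r=m["r_r"], beta_sc=m["beta_sc"], alpha_rs=m["alpha_rs"],
            alpha_sr=m["alpha_sr"], K=m["K"], drop=m["treatment_drop"],
        )

    def conversion(self) -> float:
        return float(self.data["model"]["conversion"])

    def protocol(self, **overrides) -> Protocol:
        p = {**self.data["protocol"], **overrides}
        return Protocol(**p)

    def progression_rule(self) -> ProgressionRule:
        return ProgressionRule(**self.data["progression_rule"])

    def simulation_x0(self) -> np.ndarray:
        s = self.data["simulation"]
        total = s["initial_total_fraction_of_K"] * self.data["model"]["K"]
        f = s["initial_resistant_fraction"]
        return np.array([total * (1.0 - f), total * f])

    def cohort_spec(self) -> CohortSpec:
        m, c = self.data["model"], self.data["cohort"]
        return CohortSpec(
            n_adaptive=int(c.get("n_adaptive", 17)),
            n_continuous=int(c.get("n_continuous", 16)),
            r_s=m["r_s"], r_r=m["r_r"], beta_sc=m["beta_sc"], alpha_rs=m["alpha_rs"],
            alpha_sr=m["alpha_sr"], K=m["K"], treatment_drop=m["treatment_drop"],
            conversion=m["conversion"],
            noise_sigma=float(c.get("noise_sigma", 0.1)),
            horizon_days=float(self.data["simulation"]["horizon_days"]),
            stop_fraction=float(self.data["protocol"]["stop_fraction"]),
            restart_fraction=float(self.data["protocol"]["restart_fraction"]),
            seed=int(c.get("seed", 0)),
        )


STAGES = ("synth", "fit", "simulate", "analyze")


def _write_manifest(stage_dir: Path, config: RunConfig, extra: dict):
    manifest = {"config_hash": config.hash(), "seed": config.seed, **extra}
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_pipeline(config: RunConfig, out_dir, stages: Optional[Sequence[str]] = None) -> dict:
    """Execute the requested stages in order, each writing outputs + manifest."""
    from . import fitting, outcomes, synthetic_data

    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError("unknown stages: %s" % sorted(unknown))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    if "synth" in stages:
        d = out / "cohort"
        d.mkdir(exist_ok=True)
        synthetic_data.generate_cohort(config.cohort_spec(), out_dir=d)
        _write_manifest(d, config, {"stage": "synth"})
        report["synth"] = str(d)

    if "fit" in stages:
        cohort_csv = out / "cohort" / "cohort.csv"
        if not cohort_csv.exists():
            raise FileNotFoundError(
                "fit stage needs %s; run the synth stage first (or point --out at a "
                "directory containing its outputs)" % cohort_csv
            )
        patients = fitting.read_patient_csv(cohort_csv)
        sens, res = [], []
        for s in patients:
            try:
                sens.append(fitting.estimate_sensitive_rate(s))
            except fitting.InsufficientDataError:
                pass
            if s.cohort == "continuous" and s.progression_day is not None:
                try:
                    res.append(fitting.estimate_resistant_rate(s))
                except fitting.InsufficientDataError:
                    pass
        r_s = fitting.pool_rates(sens)
        r_r = fitting.pool_rates(res) if res else config["model"]["r_r"]
        fcfg = config.data.get("fit", {})
        fit = fitting.fit_cohort(
            patients, r_s, r_r,
            K=config["model"]["K"], conversion=config.conversion(),
            beta_bounds=tuple(fcfg.get("beta_bounds", (1.0, 20.0))),
            alpha_bounds=tuple(fcfg.get("alpha_bounds", (0.5, 12.0))),
            n_coarse=int(fcfg.get("n_coarse", 7)),
            n_refine=int(fcfg.get("n_refine", 5)),
            polish=bool(fcfg.get("polish", True)),
            min_obs=int(fcfg.get("min_obs", 5)),
        )
        d = out / "fit"
        d.mkdir(exist_ok=True)
        fit.to_json(d / "fit.json")
        fit.surface.to_csv(d / "objective_surface.csv", index=False)
        _write_manifest(d, config, {"stage": "fit", "r_s": r_s, "r_r": r_r})
        report["fit"] = str(d)

    if "simulate" in stages:
        from .protocols import run_protocol

        d = out / "simulate"
        d.mkdir(exist_ok=True)
        params = config.model_params()
        x0 = config.simulation_x0()
        horizon = float(config["simulation"]["horizon_days"])
        summary = {}
        for name, proto in (
            ("adaptive", config.protocol()),
            ("continuous", Protocol(kind="continuous")),
        ):
            sim = run_protocol(params, x0, proto, horizon,
                               conversion=config.conversion(), rule=config.progression_rule())
            sim.trajectory.to_frame(run_id=name, conversion=config.conversion()).to_csv(
                d / ("trajectory_%s.csv" % name), index=False
            )
            summary[name] = {
                "ttp_days": sim.ttp_days,
                "n_cycles": sim.n_cycles,
                "fraction_time_on": sim.fraction_time_on,
                "resistant_extinct_cycle": sim.resistant_extinct_cycle,
            }
        with open(d / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _write_manifest(d, config, {"stage": "simulate"})
        report["simulate"] = str(d)

    if "analyze" in stages:
        cohort_dir = out / "cohort"
        if not (cohort_dir / "ground_truth.json").exists():
            raise FileNotFoundError(
                "analyze stage needs %s; run the synth stage first" % (cohort_dir / "ground_truth.json")
            )
        truth = pd.read_json(cohort_dir / "ground_truth.json")
        horizon = float(config["simulation"]["horizon_days"])
        records = {"adaptive": [], "continuous": []}
        for _, row in truth.iterrows():
            t = row["ttp_days"]
            event = pd.notna(t)
            records[row["cohort"]].append(
                outcomes.SurvivalRecord(
                    patient_id=row["patient_id"], arm=row["cohort"],
                    time_days=float(t) if event else horizon, event=bool(event),
                )
            )
        d = out / "analyze"
        d.mkdir(exist_ok=True)
        km_tables = {}
        for arm, recs in records.items():
            km = outcomes.km_curve(recs)
            km.table.to_csv(d / ("km_%s.csv" % arm), index=False)
            km_tables[arm] = km
        stat, p = outcomes.logrank(records["adaptive"], records["continuous"])
        kw_stat, kw_p = outcomes.kruskal_wallis(
            truth.loc[truth["cohort"] == "adaptive", "baseline_psa_true"].to_list(),
            truth.loc[truth["cohort"] == "continuous", "baseline_psa_true"].to_list(),
        )
        tt = truth.copy()
        tt["ttp_days"] = tt["ttp_days"].fillna(horizon)
        tvr = outcomes.ttp_vs_resistance(
            tt.rename(columns={"cohort": "arm"})[["resistant_fraction", "ttp_days", "arm"]]
        )
        results = {
            "logrank": {"statistic": stat, "p": p},
            "kruskal_wallis_baseline_psa": {"H": kw_stat, "p": kw_p},
            "median_ttp_days": {
                arm: km_tables[arm].median for arm in km_tables
            },
            "ttp_vs_resistance": tvr,
        }
        with open(d / "test_results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=str)
        _plot_analysis(d, km_tables, tt)
        _write_manifest(d, config, {"stage": "analyze"})
        report["analyze"] = str(d)

    return report


def _plot_analysis(out_dir: Path, km_tables: dict, truth: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for arm, km in km_tables.items():
        axes[0].step(km.table["time"], km.table["survival"], where="post", label=arm)
    axes[0].set_xlabel("days")
    axes[0].set_ylabel("progression-free fraction")
    axes[0].set_ylim(0, 1.02)
    axes[0].legend()
    for arm, grp in truth.groupby("cohort"):
        axes[1].scatter(grp["resistant_fraction"], grp["ttp_days"], label=arm, s=18)
    axes[1].set_xlabel("initial resistant fraction")
    axes[1].set_ylabel("TTP (days)")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "summary.png", dpi=110)
    plt.close(fig)
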