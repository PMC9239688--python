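"""Two-step estimation: log-linear slopes, pooling, nested cohort fit."""

import numpy as np
import pandas as pd
import pytest

from adaptlv.fitting import (
    CohortFit,
    InsufficientDataError,
    PatientSeries,
    _DEFAULT_STARTS,
    _model_psa,
    _prepare_patient,
    compare_rate_sets,
    estimate_resistant_rate,
    estimate_sensitive_rate,
    fit_cohort,
    pool_rates,
    retrospective_protocol_swap,
)
from adaptlv.model_core import LVParams, default_params, integrate
from adaptlv.protocols import Protocol
from adaptlv.synthetic_data import CohortSpec, exponential_series, generate_cohort


def series_from_frame(df, pid="P1", cohort="adaptive", on=0, progression_day=None):
    obs = df.copy()
    obs["on_therapy"] = on
    return PatientSeries(
        patient_id=pid, cohort=cohort, observations=obs,
        baseline_psa=float(obs["psa"].iloc[0]), progression_day=progression_day,
    )


MONTHLY = np.arange(0.0, 140.0, 28.0)  # five monthly visits


class TestSensitiveRate:
    def test_recovers_published_sensitive_rate_from_exponential_series(self):
        s = series_from_frame(exponential_series(5.0, 0.0156, MONTHLY))
        est = estimate_sensitive_rate(s)
        assert est.rate == pytest.approx(0.0156, rel=1e-6)
        assert est.n_points == 5

    def test_constant_series_gives_zero_rate(self):
        s = series_from_frame(pd.DataFrame({"day": MONTHLY, "psa": 5.0}))
        assert estimate_sensitive_rate(s).rate == pytest.approx(0.0)

    def test_insufficient_points_rejected(self):
        s = series_from_frame(exponential_series(5.0, 0.0156, MONTHLY[:2]))
        with pytest.raises(InsufficientDataError):
            estimate_sensitive_rate(s)

    def test_low_burden_logistic_series_within_five_percent(self):
        # the estimator assumes exponential growth; at <=5% of K the logistic
        # correction biases the slope down by only a few percent
        p = default_params(beta_sc=1.0)
        traj = integrate(p, [100.0, 0.0], False, MONTHLY)
        s = series_from_frame(pd.DataFrame({"day": MONTHLY, "psa": traj.total / 200.0}))
        est = estimate_sensitive_rate(s)
        assert est.rate == pytest.approx(0.0156, rel=0.05)

    def test_uses_only_pre_therapy_observations(self):
        pre = exponential_series(5.0, 0.0156, np.array([-84.0, -56.0, -28.0, 0.0]))
        post = pd.DataFrame({"day": [28.0, 56.0], "psa": [2.0, 1.0]})
        obs = pd.concat([pre, post], ignore_index=True)
        obs["on_therapy"] = [0, 0, 0, 1, 1, 1]
        s = PatientSeries("P1", "adaptive", obs, baseline_psa=5.0)
        assert estimate_sensitive_rate(s).rate == pytest.approx(0.0156, rel=1e-6)


class TestResistantRate:
    def test_recovers_published_resistant_rate(self):
        days = 300.0 + MONTHLY
        s = series_from_frame(exponential_series(8.0, 0.0091, days), progression_day=299.0)
        est = estimate_resistant_rate(s)
        assert est.rate == pytest.approx(0.0091, rel=1e-6)

    def test_declining_series_flagged_not_rejected(self):
        days = 300.0 + MONTHLY
        s = series_from_frame(exponential_series(8.0, -0.004, days), progression_day=299.0)
        est = estimate_resistant_rate(s)
        assert est.rate < 0
        assert "declining" in est.note

    def test_requires_progression_day(self):
        s = series_from_frame(exponential_series(8.0, 0.0091, MONTHLY))
        with pytest.raises(InsufficientDataError):
            estimate_resistant_rate(s)


class TestPooling:
    def test_single_estimate_is_itself(self):
        s = series_from_frame(exponential_series(5.0, 0.0156, MONTHLY))
        est = estimate_sensitive_rate(s)
        assert pool_rates([est]) == est.rate

    def test_mean_of_two(self):
        e1 = estimate_sensitive_rate(series_from_frame(exponential_series(5, 0.01, MONTHLY)))
        e2 = estimate_sensitive_rate(series_from_frame(exponential_series(5, 0.02, MONTHLY)))
        assert pool_rates([e1, e2]) == pytest.approx(0.015, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            pool_rates([])

    def test_jittered_cohort_pools_to_generating_rate(self):
        rng = np.random.default_rng(42)
        n = 20
        rates = 0.0156 * np.exp(rng.normal(0, 0.1, n))
        ests = [
            estimate_sensitive_rate(series_from_frame(exponential_series(5.0, r, MONTHLY)))
            for r in rates
        ]
        pooled = pool_rates(ests)
        se = rates.std(ddof=1) / np.sqrt(n)
        assert abs(pooled - 0.0156) < 3 * se + 1e-12

    def test_sensitive_vs_resistant_rate_sets_differ(self):
        rng = np.random.default_rng(0)
        sens = [
            estimate_sensitive_rate(series_from_frame(exponential_series(5, r, MONTHLY)))
            for r in 0.0156 * np.exp(rng.normal(0, 0.1, 10))
        ]
        res = [
            estimate_sensitive_rate(series_from_frame(exponential_series(5, r, MONTHLY)))
            for r in 0.0091 * np.exp(rng.normal(0, 0.1, 10))
        ]
        stat, p = compare_rate_sets(sens, res)
        assert p < 0.05


class TestCohortFitRecovery:
    def test_step_one_rates_recovered_from_noiseless_cohort(self, noiseless_fit):
        assert noiseless_fit["r_s"] == pytest.approx(0.0156, rel=1e-6)
        assert noiseless_fit["r_r"] == pytest.approx(0.0091, rel=1e-6)

    def test_patient_wide_pair_recovered(self, noiseless_fit):
        fit = noiseless_fit["fit"]
        assert fit.beta_sc == pytest.approx(8.0, rel=0.02)
        assert fit.alpha_rs == pytest.approx(6.0, rel=0.02)
        assert fit.flat_directions == []

    def test_initial_conditions_recovered(self, noiseless_fit, noiseless_cohort):
        fit = noiseless_fit["fit"]
        merged = fit.per_patient.merge(
            noiseless_cohort.truth[["patient_id", "x_s0", "x_r0"]],
            on="patient_id", suffixes=("", "_true"),
        )
        assert np.allclose(merged["x_s0"], merged["x_s0_true"], rtol=0.02, atol=5.0)
        assert np.allclose(merged["x_r0"], merged["x_r0_true"], rtol=0.02, atol=5.0)

    def test_constraints_hold_and_minimum_is_global_over_surface(self, noiseless_fit):
        fit = noiseless_fit["fit"]
        assert (fit.per_patient["x_s0"] >= 0).all()
        assert (fit.per_patient["x_r0"] >= 0).all()
        assert (fit.per_patient["x_s0"] + fit.per_patient["x_r0"] <= fit.K).all()
        assert fit.objective <= fit.surface["objective"].min() + 1e-9

    def test_noisy_recovery_within_quarter(self):
        """10% multiplicative PSA noise: shared pair recovered within 25%."""
        spec = CohortSpec(
            seed=21, n_adaptive=3, n_continuous=3, noise_sigma=0.1,
            rate_jitter_sigma=0.0, resistant_fraction_range=(0.05, 0.35),
        )
        bundle = generate_cohort(spec)
        fit = fit_cohort(bundle.patients, 0.0156, 0.0091, n_coarse=5, n_refine=3,
                         polish_maxfev=40)
        assert fit.beta_sc == pytest.approx(8.0, rel=0.25)
        assert fit.alpha_rs == pytest.approx(6.0, rel=0.25)


class TestBruteForceOracle:
    def test_nested_optimizer_matches_exhaustive_inner_grid(self, noiseless_cohort):
        """Single patient, coarse outer grid: the nested inner optimiser picks
        the same outer minimiser as an exhaustive inner grid search.  Uses the
        long-cycling adaptive patient, whose rich PSA record identifies the
        outer pair sharply."""
        series = max(
            (s for s in noiseless_cohort.patients if s.cohort == "adaptive"),
            key=lambda s: len(s.on_study()),
        )
        fd = _prepare_patient(series, 5)
        K = 10_000.0
        r = np.array([0.0156, 0.0091])
        K_arr = np.array([K, K])
        drop = np.array([0.9, 0.0])
        betas = np.geomspace(1.0, 20.0, 3)
        alphas = np.geomspace(0.5, 12.0, 3)

        brute = np.empty((3, 3))
        totals = np.linspace(500.0, 9500.0, 41)
        fracs = np.linspace(0.0, 1.0, 21)
        for i, b in enumerate(betas):
            for j, a in enumerate(alphas):
                am = np.array([[1.0, 1.0], [a, 1.0]])
                best = np.inf
                for tot in totals:
                    for f in fracs:
                        x0 = np.array([tot * (1 - f), tot * f])
                        m = _model_psa(fd, r, K_arr, am, drop, b, x0, 200.0, 0.25)
                        best = min(best, float(np.sum((m - fd.psa) ** 2)))
                brute[i, j] = best

        fit = fit_cohort([series], 0.0156, 0.0091, n_coarse=3, n_refine=2, polish=False)
        coarse = fit.surface[fit.surface["stage"] == "coarse"]
        nested = coarse.pivot(index="beta_sc", columns="alpha_rs", values="objective").to_numpy()
        assert np.unravel_index(np.argmin(nested), nested.shape) == np.unravel_index(
            np.argmin(brute), brute.shape
        )
        # the optimised inner fit is at least as good as the brute grid best
        assert nested.min() <= brute.min() + 1e-6


class TestFlatDirections:
    def test_pure_sensitive_cohort_reports_alpha_unidentifiable(self):
        spec = CohortSpec(
            seed=11, n_adaptive=3, n_continuous=0, noise_sigma=0.0,
            rate_jitter_sigma=0.0, resistant_fraction_range=(0.0, 0.0),
        )
        bundle = generate_cohort(spec)
        fit = fit_cohort(bundle.patients, 0.0156, 0.0091, n_coarse=3, n_refine=2)
        assert "alpha_rs" in fit.flat_directions
        assert fit.beta_sc == pytest.approx(8.0, rel=0.05)


class TestRetrospectiveSwap:
    def test_identity_swap_reproduces_observed_psa(self, noiseless_fit, noiseless_cohort):
        fit = noiseless_fit["fit"]
        series = next(s for s in noiseless_cohort.patients if s.cohort == "continuous")
        sim = retrospective_protocol_swap(fit, series.patient_id, Protocol(kind="continuous"),
                                          horizon_days=1800.0)
        obs = series.on_study()
        obs = obs[obs["day"] <= series.progression_day]
        model = sim.trajectory.at(obs["day"].to_numpy()).sum(axis=1) / fit.conversion
        assert np.allclose(model, obs["psa"].to_numpy(), rtol=0.02)

    def test_adaptive_counterfactual_extends_control(self, noiseless_fit):
        fit = noiseless_fit["fit"]
        cont = fit.per_patient[fit.per_patient["cohort"] == "continuous"]
        pid = cont.sort_values("resistant_fraction").iloc[0]["patient_id"]
        sim_ad = retrospective_protocol_swap(fit, pid, Protocol(kind="adaptive_ideal"))
        sim_ct = retrospective_protocol_swap(fit, pid, Protocol(kind="continuous"))
        assert sim_ad.ttp_or_horizon > sim_ct.ttp_or_horizon

    def test_nearly_pure_resistant_patient_gains_nothing(self, noiseless_fit):
        fit = noiseless_fit["fit"]
        fit2 = CohortFit(
            r_s=fit.r_s, r_r=fit.r_r, beta_sc=fit.beta_sc, alpha_rs=fit.alpha_rs,
            objective=0.0,
            per_patient=pd.DataFrame(
                [{"patient_id": "R1", "cohort": "continuous", "x_s0": 100.0,
                  "x_r0": 6000.0, "total0": 6100.0, "resistant_fraction": 0.984,
                  "sse": 0.0, "n_obs": 10}]
            ),
            surface=fit.surface, flat_directions=[], conversion=fit.conversion,
            K=fit.K, treatment_drop=fit.treatment_drop,
        )
        t_ad = retrospective_protocol_swap(fit2, "R1", Protocol(kind="adaptive_ideal")).ttp_or_horizon
        t_ct = retrospective_protocol_swap(fit2, "R1", Protocol(kind="continuous")).ttp_or_horizon
        assert t_ad == pytest.approx(t_ct, rel=0.1)

    def test_unknown_patient_rejected(self, noiseless_fit):
        with pytest.raises(KeyError):
            retrospective_protocol_swap(noiseless_fit["fit"], "nobody", Protocol(kind="continuous"))


class TestResistanceTTPCorrelation:
    def test_initial_resistant_fraction_anticorrelates_with_ttp(self, default_cohort):
        from scipy.stats import spearmanr

        truth = default_cohort.truth.copy()
        truth["ttp"] = truth["ttp_days"].fillna(1800.0)
        for arm in ("adaptive", "continuous"):
            g = truth[truth["cohort"] == arm]
            rho, p = spearmanr(g["resistant_fraction"], g["ttp"])
            assert rho < 0
            assert p < 0.05
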