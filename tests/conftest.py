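import numpy as np
import pytest

from adaptlv.fitting import fit_cohort, pool_rates, estimate_resistant_rate, estimate_sensitive_rate
from adaptlv.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size two-arm cohort at the default study conditions."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_spec():
    return CohortSpec(
        seed=3,
        n_adaptive=5,
        n_continuous=5,
        noise_sigma=0.0,
        rate_jitter_sigma=0.0,
        resistant_fraction_range=(0.05, 0.35),
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_cohort):
    """Two-step fit of the noiseless ten-patient cohort (shared: it is slow)."""
    patients = noiseless_cohort.patients
    sens = [estimate_sensitive_rate(s) for s in patients]
    res = [
        estimate_resistant_rate(s)
        for s in patients
        if s.cohort == "continuous" and s.progression_day is not None
    ]
    r_s, r_r = pool_rates(sens), pool_rates(res)
    fit = fit_cohort(patients, r_s, r_r)
    return {"fit": fit, "r_s": r_s, "r_r": r_r}
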