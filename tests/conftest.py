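import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from epidex import CohortConfig, generate_cohort
from epidex.config import McmcSettings
from epidex.outcomes import derive_outcomes, resolve_confirmation

hyp_settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_settings():
    return McmcSettings(n_chains=2, n_warmup=500, n_draws=800, seed=7)


@pytest.fixture(scope="session")
def loop_settings():
    """Lean settings for replicate loops."""
    return McmcSettings(n_chains=1, n_warmup=300, n_draws=600, seed=7)


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort: design risks, site heterogeneity, missingness."""
    return generate_cohort(CohortConfig(n_participants=2000, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully followed cohort (no loss, no safety events) for truth-table checks."""
    return generate_cohort(CohortConfig(
        n_participants=2000, seed=43, loss_to_followup=0.0, withdrawal_rate=0.0,
        safety_event_rate=0.0))


@pytest.fixture(scope="session")
def cohort_outcomes(cohort):
    ev = resolve_confirmation(cohort.events, cohort.participants)
    return derive_outcomes(cohort.participants, ev)


@pytest.fixture(scope="session")
def clean_outcomes(clean_cohort):
    ev = resolve_confirmation(clean_cohort.events, clean_cohort.participants)
    return derive_outcomes(clean_cohort.participants, ev)


def two_arm_frame(n0, k0, n1, k1):
    """Collapsed two-arm dataset as a long DataFrame."""
    return pd.DataFrame({
        "y": np.r_[np.ones(k0), np.zeros(n0 - k0), np.ones(k1), np.zeros(n1 - k1)].astype(int),
        "arm": np.r_[np.zeros(n0), np.ones(n1)],
    })
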