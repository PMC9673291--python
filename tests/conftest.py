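import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from psmcea.config import default_config
from psmcea.pipeline import fit_survival, load_survival_datasets
from psmcea.synthetic import CohortSpec, simulate_ipd


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def lognormal_cohort():
    """Moderate synthetic cohort with ~20% administrative censoring."""
    spec = CohortSpec(
        n_patients=500,
        endpoint="PFS",
        family="log-normal",
        params=(math.log(4.6), 1.1),
        accrual_months=6.0,
        followup_months=18.0,
        seed=7,
    )
    return simulate_ipd(spec)


@pytest.fixture(scope="session")
def fitted_model(config):
    """Selected parametric fits for the default synthetic cohorts (shared
    across engine/pipeline tests to avoid refitting)."""
    datasets = load_survival_datasets(config, seed=11)
    fits, selected = fit_survival(config, datasets)
    return {"datasets": datasets, "fits": fits, "selected": selected}
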