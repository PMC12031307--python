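import numpy as np
import pytest
from hypothesis import settings

from bisfruit import (
    CohortParameters,
    ECParameters,
    FrequencyGrid,
    StudyDesign,
    generate_cohort,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def reference_params():
    """A physically plausible fruit: electrode block small, tissue dominant."""
    return ECParameters.from_array([500.0, 2e-6, 0.85, 2e4, 6e3, 8e-7, 0.80])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (8 fruit, 24 spectra) for fast end-to-end tests."""
    design = StudyDesign(n_per_group=2, seed=11)
    records, spectra = generate_cohort(design)
    return design, records, spectra


@pytest.fixture(scope="session")
def medium_cohort():
    """A mid-size cohort (40 fruit) for distributional checks."""
    design = StudyDesign(n_per_group=10, seed=23)
    records, spectra = generate_cohort(design)
    return design, records, spectra


def draw_cohortlike_params(rng: np.random.Generator) -> ECParameters:
    """Random circuit parameters from the cohort's baseline distribution."""
    cp = CohortParameters()
    loc, sd = cp.baseline_log_median, cp.baseline_log_sd
    v = {k: float(np.exp(rng.normal(loc[k], sd[k]))) for k in loc}
    a_e = float(np.clip(rng.normal(0.85, 0.03), 0.5, 0.99))
    a_m = float(np.clip(rng.normal(0.80, 0.03), 0.5, 0.99))
    return ECParameters.from_array(
        [v["r_e"], v["q_e"], a_e, v["r_ex"], v["r_i"], v["q_m"], a_m]
    )
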