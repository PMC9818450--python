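import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import survscreen as ss

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-sample cohort with one strong prognostic gene (G0000)."""
    cfg = ss.SimulationConfig(
        name="small", n_samples=60, n_genes=10,
        planted={0: float(np.log(2.5))}, censoring=0.3, seed=11,
    )
    cohort, truth = ss.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def trio():
    """Study-scale trio (69/77/134 samples) with the planted gene G0000."""
    return ss.generate_multi_cohort(ss.default_trio_configs(n_genes=30), master_seed=5)


@pytest.fixture()
def no_tie_survival():
    """Moderate censored dataset with distinct event times (no ties)."""
    rng = np.random.default_rng(3)
    n = 80
    x = rng.normal(size=n)
    t_event = 20 * (-np.log(rng.random(n)) / np.exp(0.6 * x)) ** (1 / 1.2)
    c = rng.uniform(5, 60, n)
    times = np.minimum(t_event, c)
    events = (t_event <= c).astype(int)
    return x, times, events
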