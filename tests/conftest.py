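import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seasonmed as sm
from seasonmed.photoperiod import annotate_photoperiod

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def null_structure_config(n=5000, seed=101, **overrides):
    """Generator config with no seasonal or mediation structure."""
    zero = {k: 0.0 for k in sm.synthetic.STRUCTURES}
    base = dict(
        n_participants=n,
        seed=seed,
        true_amplitude=dict(zero),
        path_a=dict(zero),
        path_b={"female": 0.0, "male": 0.0},
        path_c_prime={"female": 0.0, "male": 0.0},
    )
    base.update(overrides)
    return sm.GeneratorConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """A moderate cohort under the default (study-like) conditions."""
    cfg = sm.GeneratorConfig(n_participants=4000, seed=11)
    table, truth = sm.generate_cohort(cfg)
    return annotate_photoperiod(table), truth


@pytest.fixture(scope="session")
def female_cohort():
    """All-female cohort with the default female mediation paths."""
    cfg = sm.GeneratorConfig(n_participants=4000, seed=23, female_fraction=1.0)
    table, truth = sm.generate_cohort(cfg)
    return annotate_photoperiod(table), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
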