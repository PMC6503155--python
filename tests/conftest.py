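import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

import isobold as ib


@pytest.fixture(scope="session")
def small_config():
    """A small noisy cohort configuration used across tests."""
    return ib.CohortConfig(n_subjects=4, grid_shape=(8, 8, 8), n_regions=8, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    parc, subjects = ib.simulate_cohort(small_config)
    return small_config, parc, subjects


@pytest.fixture(scope="session")
def noiseless_subject():
    """One noiseless subject on a small grid with impulse responses only
    (no peak shift, no prolongation), so BOLD lies exactly in the span of
    the GLM design."""
    effects = []
    amps = [(1.0, 0.5), (0.5, 1.0), (0.8, 0.8), (0.3, 0.9)]
    for i, (ap, at) in enumerate(amps):
        effects.append(ib.RegionEffect(i + 1, amp_pain=ap, amp_tactile=at,
                                       intensity_slope=0.0))
    for i in range(4, 8):
        effects.append(ib.RegionEffect(i + 1, amp_pain=0.8, amp_tactile=0.8,
                                       intensity_slope=0.15))
    cfg = ib.CohortConfig(n_subjects=1, grid_shape=(8, 8, 8), n_regions=8,
                          region_effects=effects, noise=ib.NoiseModel.silent(),
                          seed=21)
    parc = ib.simulate_parcellation(cfg)
    subj = ib.simulate_subject(cfg, parc, 0)
    return cfg, parc, subj


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
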