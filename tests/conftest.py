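import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnu2comb.locus import build_haplotype, default_locus_map
from rnu2comb.simulate import CohortConfig, simulate_fibre, zero_noise

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lmap():
    return default_locus_map()


@pytest.fixture(scope="session")
def hap19(lmap):
    return build_haplotype(lmap, 19)


def make_config(**overrides) -> CohortConfig:
    base = dict(fibre_length_mean_kb=900.0, fibre_length_sd_kb=0.0,
                stretch_mean=2.0, orientation_prob=0.0)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture
def clean_fibre_factory(lmap):
    """Zero-noise, forward-orientation fibres covering a named region."""

    def factory(n=19, region="full", stretch=2.0, seed=0, length_kb=900.0):
        hap = build_haplotype(lmap, n)
        cfg = zero_noise(make_config(stretch_mean=stretch,
                                     fibre_length_mean_kb=length_kb))
        rng = np.random.default_rng(seed)
        return simulate_fibre(hap, cfg, rng, require_region=region), hap

    return factory
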