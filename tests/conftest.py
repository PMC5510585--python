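import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from introscan import simdata

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def small_config(seed: int = 7, **kw) -> simdata.SimConfig:
    """A fast, small study for I/O and smoke tests."""
    base = dict(
        seed=seed,
        n_sites=400,
        chrom_length_bp=4_000_000,
        tract_bp=(1_800_000, 2_200_000),
        tract_site_fraction=0.25,
        founder_pool=100,
        n_ref_a=6,
        n_ref_b=8,
        n_admixed=5,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


def selection_config(seed: int, **kw) -> simdata.SimConfig:
    """The dense candidate-region study used for the haplotype scans."""
    base = dict(
        seed=seed,
        n_sites=2500,
        chrom_length_bp=6_000_000,
        tract_bp=(2_700_000, 3_300_000),
        tract_site_fraction=0.3,
        aim_fraction=0.05,
        background_admixture=0.02,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size default study, shared across read-only tests."""
    return simdata.simulate(simdata.SimConfig(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
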