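import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibrilkit import (
    DistortionSpec,
    FibrilSpec,
    build_ideal_fibril,
    make_trajectory,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return FibrilSpec()


@pytest.fixture(scope="session")
def pentamer(default_spec):
    """The default 5-chain, 32-residue synthetic cross-beta stack."""
    return build_ideal_fibril(default_spec)


@pytest.fixture(scope="session")
def small_spec():
    """A cheap 3-chain, 12-residue stack for fast unit tests."""
    return FibrilSpec(
        n_chains=3,
        n_residues=12,
        segments=(6, 6),
        sequence=tuple(["GLY"] * 12),
        first_residue_id=1,
    )


@pytest.fixture(scope="session")
def small_fibril(small_spec):
    return build_ideal_fibril(small_spec)


@pytest.fixture(scope="session")
def small_stable_traj(small_fibril):
    ds = DistortionSpec(mode="stable", amplitude=0.005, n_frames=12, seed=7)
    return make_trajectory(small_fibril, ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
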