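import numpy as np
import pytest

from seafloorbgc.synthetic import (
    SyntheticGridSpec,
    SyntheticProfileSpec,
    generate_grids,
    generate_profile,
)


@pytest.fixture(scope="session")
def clean_profile_spec() -> SyntheticProfileSpec:
    """Noise-free O2 profile spec used for round-trip inversion tests."""
    return SyntheticProfileSpec(
        species="O2",
        surface_conc=0.15,
        rate0=2e-6,
        efold=20.0,
        depth_max=100.0,
        n_samples=60,
        noise_sd=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_profile(clean_profile_spec):
    return generate_profile(clean_profile_spec)


@pytest.fixture(scope="session")
def coarse_grids():
    """Co-registered synthetic heatflow/thickness/age grids at 4 degrees."""
    return generate_grids(SyntheticGridSpec(resolution_deg=4.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
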