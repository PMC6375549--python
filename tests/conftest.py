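import numpy as np
import pytest

from rotorflim.synthetic import (
    DecaySpec,
    TrajectorySpec,
    generate_brownian_trajectory,
    generate_decay,
    generate_toy_bilayer,
)


@pytest.fixture(scope="session")
def mono_spec() -> DecaySpec:
    """Mono-exponential control decay in the default acquisition regime."""
    return DecaySpec(lifetimes_ps=(2473.0,), total_counts=1e5, seed=11)


@pytest.fixture(scope="session")
def mono_decay(mono_spec):
    return generate_decay(mono_spec)


@pytest.fixture(scope="session")
def default_irf(mono_spec):
    return mono_spec.build_irf()


@pytest.fixture(scope="session")
def toy_bilayer():
    """Small constructed bilayer with beta = 30 degrees everywhere."""
    return generate_toy_bilayer(beta_deg=30.0, n_per_leaflet=9, n_carbons=2)


@pytest.fixture(scope="session")
def brownian_traj():
    spec = TrajectorySpec(
        n_atoms=150, diffusion_nm2_per_ps=1e-5, dt_ps=100.0, n_frames=1500, seed=4
    )
    return spec, generate_brownian_trajectory(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
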