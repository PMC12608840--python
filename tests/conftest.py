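import numpy as np
import pytest

from sipcop import Anthropometry, SeatGeometry, SimulationConfig, noiseless


@pytest.fixture
def anthro() -> Anthropometry:
    """Fixed reference individual with vertical trunk CoM and y-aligned
    upper-leg CoM (the alignment the closed-form magnitudes assume)."""
    return Anthropometry(
        trunk_com=np.array([0.0, 0.0, 30.0]),
        upper_leg_com=np.array([0.0, 17.0, 0.0]),
        trunk_mass_fraction=0.55,
        upper_leg_mass_fraction=0.25,
        upper_leg_length=40.0,
        hip_half_width=8.5,
        it_offset=5.0,
        upright_com_y=10.0,
        body_mass=70.0,
    )


@pytest.fixture
def geom() -> SeatGeometry:
    return SeatGeometry()


@pytest.fixture
def exact_cfg(anthro, geom) -> SimulationConfig:
    """Noise-free generator on a mat clock commensurate with the load-cell
    and IMU clocks (12.5 Hz vs 125/100 Hz), so nearest-in-time pairing has
    zero offset and forward-model consistency holds to float precision."""
    return noiseless(
        SimulationConfig(anthropometry=anthro, geometry=geom, seed=11, mat_hz=12.5)
    )


def random_anthropometry(rng: np.random.Generator) -> Anthropometry:
    """Draw a valid random individual for property tests (closed-form
    alignment: T vertical, U along y)."""
    L = rng.uniform(30.0, 48.0)
    return Anthropometry(
        trunk_com=np.array([0.0, 0.0, rng.uniform(24.0, 38.0)]),
        upper_leg_com=np.array([0.0, rng.uniform(12.0, 0.48 * L), 0.0]),
        trunk_mass_fraction=rng.uniform(0.45, 0.62),
        upper_leg_mass_fraction=rng.uniform(0.18, 0.3),
        upper_leg_length=L,
        hip_half_width=rng.uniform(6.0, 11.0),
        it_offset=rng.uniform(0.0, 0.45 * L),
        upright_com_y=rng.uniform(4.0, 0.6 * L),
        body_mass=rng.uniform(45.0, 110.0),
    )
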