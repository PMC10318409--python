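import numpy as np
import pytest

from flimox import fit_stern_volmer, synthesis


@pytest.fixture(scope="session")
def calib_30c():
    """Two-point RTDP calibration at 30°C (τ0 = 526 ns, τ100% = 144 ns)."""
    return fit_stern_volmer(526.0, 144.0, 1.0, 30.0)


@pytest.fixture(scope="session")
def calib_25c():
    return fit_stern_volmer(573.0, 160.0, 1.0, 25.0)


@pytest.fixture(scope="session")
def small_colony():
    """A 6 h aerobic colony reused across tests (deterministic, seed 3)."""
    return synthesis.simulate_colony(seed=3, duration_h=6.0)


@pytest.fixture(scope="session")
def rendered_colony(small_colony):
    return synthesis.render_frames(small_colony, pixel_size_um=0.1)


@pytest.fixture(scope="session")
def switch_experiment():
    """One anaerobic-to-aerobic switch chamber plus an aerobic reference."""
    anaerobic = synthesis.make_experiment("anaerobic_switch", seed=11, n_chambers=1)
    aerobic = synthesis.make_experiment("aerobic", seed=11, n_chambers=1)
    return anaerobic, aerobic


def single_harmonic_stack(
    tau_ns: float,
    f_hz: float = 550e3,
    k: int = 8,
    shape: tuple = (4, 4),
    dc: float = 1000.0,
):
    """Noise-free modulated stack for a mono-exponential lifetime."""
    from flimox.fdflim import ModulatedFrameStack

    omega = 2 * np.pi * f_hz
    phi = np.arctan(omega * tau_ns * 1e-9)
    m = 1.0 / np.sqrt(1.0 + (omega * tau_ns * 1e-9) ** 2)
    angles = 2 * np.pi * np.arange(k) / k
    series = dc * (1.0 + m * np.cos(angles - phi))
    pixels = np.broadcast_to(series[:, None, None], (k, *shape)).copy()
    return ModulatedFrameStack(pixels=pixels, modulation_frequency_hz=f_hz)
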