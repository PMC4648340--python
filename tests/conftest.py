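import numpy as np
import pytest

from simqc.synth import (SimScenario, generate_bead_field, generate_raw_sim,
                         generate_recon_like)


def on_grid_scenario(n=64, kx=8, ky=2, n_angles=1, **kw):
    """Scenario whose stripe frequency lands exactly on FFT grid points for
    the first angle, so Fourier-phase estimates are machine-precision exact."""
    theta = float(np.degrees(np.arctan2(ky, kx)))
    kw.setdefault("shape", (5, n, n))
    kw.setdefault("axial_period_um", 100.0)   # envelope ~1 over the stack
    return SimScenario(k=float(np.hypot(kx, ky)) / n, n_angles=n_angles,
                       angles_deg=tuple(theta + 60.0 * a for a in range(3)),
                       **kw)


@pytest.fixture(scope="session")
def bead_density():
    return generate_bead_field((9, 64, 64), 150, seed=7)


@pytest.fixture(scope="session")
def noisy_raw(bead_density):
    """A realistic noisy acquisition used by several checks."""
    sc = SimScenario(shape=(9, 64, 64), m=0.8, poisson=True, read_noise=2.0,
                     seed=11)
    raw, truth = generate_raw_sim(bead_density, sc)
    return raw, truth, sc


@pytest.fixture(scope="session")
def clean_raw(bead_density):
    """Noise-free acquisition of the same bead field."""
    sc = SimScenario(shape=(9, 64, 64), m=0.8, seed=11)
    raw, truth = generate_raw_sim(bead_density, sc)
    return raw, truth, sc


@pytest.fixture()
def recon_like():
    return generate_recon_like(shape=(10, 100, 100), n_features=12,
                               feature_value=100.0, ringing_amp=50.0, seed=5)
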