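import numpy as np
import pytest

from secrbayes.data_model import CaptureHistory, TrapArray
from secrbayes.secr import FitConfig, fit_secr
from secrbayes.state_space import StateSpace
from secrbayes.synthetic import generate_scenario


@pytest.fixture(scope="session")
def coarse_scenario():
    """Full synthetic design at coarse (7.84 km^2) pixel resolution."""
    return generate_scenario(42, pixel_area_km2=7.84)


@pytest.fixture(scope="session")
def coarse_fit(coarse_scenario):
    """A short but usable SECR fit shared by sampler/diagnostics tests."""
    sc = coarse_scenario
    cfg = FitConfig(seed=7, iterations=4000, burn_in=1500)
    return fit_secr(sc.history, sc.traps, sc.state_space, cfg)


@pytest.fixture
def square_traps():
    """Four traps on a 2 km square, five occasions, all active."""
    return TrapArray(
        ("T1", "T2", "T3", "T4"),
        np.array([0.0, 2000.0, 0.0, 2000.0]),
        np.array([0.0, 0.0, 2000.0, 2000.0]),
        np.ones((4, 5), dtype=int),
    )


@pytest.fixture
def one_pixel_space():
    """Degenerate single-pixel state space centered at (500, 500)."""
    return StateSpace(
        x=np.array([500.0]),
        y=np.array([500.0]),
        ix=np.array([0]),
        iy=np.array([0]),
        nx=1,
        ny=1,
        pixel_area_km2=1.0,
        suitable=np.array([True]),
        buffer_m=100.0,
    )


def make_history(y, trap_ids=None):
    y = np.asarray(y, dtype=np.int8)
    ids = tuple(f"A{i + 1}" for i in range(y.shape[0]))
    trap_ids = trap_ids or tuple(f"T{j + 1}" for j in range(y.shape[1]))
    return CaptureHistory(y, ids, trap_ids)
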