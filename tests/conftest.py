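import numpy as np
import pytest

from thetahd.session import TRACKING_DT, TrackingSeries, compute_kinematics
from thetahd.synthetic import (CellSpec, ThetaLfpParams, TrajectoryParams,
                               simulate_cell, simulate_lfp, simulate_trajectory)


@pytest.fixture(scope="session")
def tracking():
    """One standard 8-min foraging trajectory (50 Hz, 90 cm arena)."""
    return simulate_trajectory(TrajectoryParams(seed=11))


@pytest.fixture(scope="session")
def lfp(tracking):
    """Speed-modulated theta LFP matched to the standard trajectory."""
    return simulate_lfp(tracking, ThetaLfpParams(seed=2))


@pytest.fixture(scope="session")
def hd_cell(tracking, lfp):
    """Sharply tuned non-rhythmic head-direction cell (kappa = 3)."""
    spec = CellSpec(cell_id="hd", r0=5.0, hd_pref=200.0, hd_kappa=3.0)
    return spec, simulate_cell(spec, tracking, lfp, seed=21)


@pytest.fixture(scope="session")
def theta_cell(tracking, lfp):
    """Phase-locked, non-directional theta cell (kappa_phi = 2)."""
    spec = CellSpec(cell_id="theta", r0=8.0, phase_pref=120.0, phase_kappa=2.0)
    return spec, simulate_cell(spec, tracking, lfp, seed=22)


@pytest.fixture(scope="session")
def place_cell(tracking, lfp):
    """Compact place field at the arena center, ~10 Hz peak."""
    spec = CellSpec(cell_id="place", r0=0.1, place_field=(45.0, 45.0, 8.0, 100.0))
    return spec, simulate_cell(spec, tracking, lfp, seed=23)


@pytest.fixture(scope="session")
def poisson_cell(tracking, lfp):
    """Homogeneous 5-Hz Poisson cell: the untuned null."""
    spec = CellSpec(cell_id="poisson", r0=5.0)
    return spec, simulate_cell(spec, tracking, lfp, seed=24)


@pytest.fixture()
def straight_tracking():
    """Uniform eastward motion: 0.2 cm per 20-ms sample (10 cm/s)."""
    n = 500
    t = np.arange(n) * TRACKING_DT
    x = 1.0 + 0.2 * np.arange(n)
    x = np.minimum(x, 89.0)  # stay inside the arena
    tr = TrackingSeries(t=t, x=x, y=np.full(n, 45.0), hd=np.zeros(n))
    return compute_kinematics(tr)
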