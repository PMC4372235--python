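import numpy as np
import pytest

from memtirf.sim import CellGeometry, SimConfig, Trajectory, simulate_membrane_dynamics


@pytest.fixture
def geometry():
    return CellGeometry(length=3.0, radius=0.4)


@pytest.fixture
def small_traj(geometry):
    cfg = SimConfig(
        D_free=0.02, dt=0.05, n_steps=20, n_particles=50, geometry=geometry, seed=11
    )
    return simulate_membrane_dynamics(cfg)


def make_static_trajectory(geometry, s, theta, n_frames=2, dt=0.1):
    """Trajectory with immobile particles at prescribed surface positions."""
    s = np.asarray(s, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = s.size
    cfg = SimConfig(
        D_free=0.0, dt=dt, n_steps=n_frames - 1, n_particles=n, geometry=geometry, seed=0
    )
    return Trajectory(
        s_raw=np.tile(s, (n_frames, 1)),
        arc_raw=np.tile(theta * geometry.radius, (n_frames, 1)),
        bound_site=np.full((n_frames, n), -1, dtype=np.int32),
        bleached=np.zeros((n_frames, n), dtype=bool),
        site_positions=np.empty((0, 2)),
        config=cfg,
    )
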