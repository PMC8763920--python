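import numpy as np
import pytest

from helixmsm.geometry import BackboneGeometry, build_coordinates
from helixmsm.helixcoil import HelixCoilParams, StateTrajectory


@pytest.fixture()
def small_params():
    return HelixCoilParams(n_res=3, sigma=0.1, s=2.0,
                           flip_attempts_per_frame=3, seed=1)


@pytest.fixture()
def default_params():
    """The 15-residue i,i+4 stapled reference system."""
    return HelixCoilParams(n_res=15, sigma=0.01, s=1.1, staple=(5, 9),
                           staple_bonus=2.0, flip_attempts_per_frame=15,
                           frame_dt=0.5, seed=0)


def make_state_traj(states, frame_dt=0.5):
    states = np.asarray(states, dtype=np.uint8)
    params = HelixCoilParams(n_res=states.shape[1], sigma=0.01, s=1.1,
                             frame_dt=frame_dt)
    return StateTrajectory(states=states, frame_dt=frame_dt, params=params,
                           seed=0)


@pytest.fixture()
def ideal_helix_traj():
    """One jitter-free all-helix frame of a 15-residue chain."""
    st = make_state_traj(np.ones((1, 15)))
    return build_coordinates(st, BackboneGeometry(jitter_sd=0.0), seed=0)


@pytest.fixture()
def extended_traj():
    """One jitter-free fully extended (phi = psi = 180) frame."""
    geom = BackboneGeometry(coil_phi_range=(180.0, 180.0),
                            coil_psi_range=(180.0, 180.0), jitter_sd=0.0)
    st = make_state_traj(np.zeros((1, 15)))
    return build_coordinates(st, geom, seed=0)
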