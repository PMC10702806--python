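import numpy as np
import pytest

import memlens as m


@pytest.fixture(scope="session")
def sphere_cloud():
    """Noisy scattered samples of a 320-A sphere cap (~5,000 points)."""
    spec = m.SurfaceSpec("sphere_cap", {"R": 320.0}, extent=160,
                         density=0.2, noise_sd=1.0, seed=1)
    return spec, m.gen_surface_cloud(spec)


@pytest.fixture(scope="session")
def order_trajectory():
    """500 lipids x 100 frames with chain order S_CD = 0.20."""
    spec = m.TrajectorySpec(n_lipids=500, n_frames=100, target_SCD=0.20,
                            flip_rate=0.0, seed=42)
    traj, log = m.gen_lipid_trajectory(spec)
    return spec, traj, log


def make_trajectory(frames, names, res_id, res_name, chain_id=None, box=None):
    """Assemble a LipidTrajectory from a list of per-frame coordinates."""
    coords = np.stack([np.asarray(f, dtype=float) for f in frames])
    return m.LipidTrajectory(coords, names, res_id, res_name,
                             chain_id=chain_id, box=box)


def model_trajectory(models):
    """Stack AtomModel snapshots (same topology) into a trajectory."""
    first = models[0]
    return m.LipidTrajectory(
        np.stack([mod.coords for mod in models]), first.name, first.res_id,
        first.res_name, chain_id=first.chain_id)
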