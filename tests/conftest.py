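import numpy as np
import pytest

import nrtraj as nt


@pytest.fixture(scope="session")
def ideal_helix():
    """20-residue ideal alpha-helix along +z (topology, frame)."""
    return nt.build_ideal_helix(20)


@pytest.fixture(scope="session")
def anchors():
    return nt.synthetic_anchors()


@pytest.fixture(scope="session")
def agonist_bundle(anchors):
    """Small agonist-regime bundle trajectory (100 frames, fixed seed)."""
    return nt.simulate_bundle(nt.agonist_params(n_frames=100, seed=42), anchors)


@pytest.fixture(scope="session")
def antagonist_bundle(anchors):
    return nt.simulate_bundle(nt.antagonist_params(n_frames=100, seed=42), anchors)


@pytest.fixture(scope="session")
def planted_complex():
    """Complex with one plant per interaction kind at known occupancies."""
    specs = [nt.InteractionPlantSpec(kind=k, presence_fraction=p)
             for k, p in [("hbond", 0.38), ("hydrophobic", 0.7),
                          ("pipi", 0.5), ("water_bridge", 0.25)]]
    return nt.plant_complex(specs, n_frames=100, seed=3)


def random_rigid_transform(rng):
    """Random rotation matrix + translation vector."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def transform_trajectory(traj, R, t):
    frames = [nt.Frame(index=f.index, time=f.time, coordinates=f.coordinates @ R.T + t)
              for f in traj.frames]
    return nt.Trajectory(topology=traj.topology, frames=frames,
                         replica_id=traj.replica_id, system_label=traj.system_label)
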