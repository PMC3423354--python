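import numpy as np
import pytest

from bindmode import AtomRecord, Frame, Trajectory


def make_trajectory(coords_per_frame, dt=10.0, names=None, replicate="rep"):
    """Trajectory from an (F, N, 3) array with generic atom identities."""
    coords = np.asarray(coords_per_frame, dtype=float)
    n = coords.shape[1]
    if names is None:
        names = [f"A{i}" for i in range(n)]
    atoms = [
        AtomRecord(i, names[i], "C", "UNK", i + 1, "A", coords[0, i])
        for i in range(n)
    ]
    frames = [Frame(m * dt, coords[m]) for m in range(coords.shape[0])]
    return Trajectory(atoms, frames, replicate_label=replicate)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_trajectory():
    rng = np.random.default_rng(7)
    base = rng.normal(size=(8, 3)) * 4.0
    return make_trajectory(np.repeat(base[None], 20, axis=0))


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return R.as_matrix(), rng.normal(size=3) * 10.0
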