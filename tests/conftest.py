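import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oxtraj.core import Configuration, InMemoryTrajectory, Nucleotide, Topology
from oxtraj.io_oxdna import DesignedPairs
from oxtraj import synthetic


@pytest.fixture
def duplex10():
    """Ideal 10-bp B-form duplex: (topology, configuration, designed pairs)."""
    return synthetic.build_duplex(synthetic.HelixSpec(n_bp=10))


@pytest.fixture
def duplex10_traj(duplex10):
    topo, cfg, pairs = duplex10
    traj = synthetic.perturb(
        cfg, synthetic.NoiseSpec(sigma=0.03, n_frames=10, seed=42), topology=topo
    )
    return topo, traj, pairs


def make_two_duplex_fixture(angle_deg: float, n_bp: int = 10, offset=(8.0, 0.0, 0.0)):
    """Two rigid duplexes, the second rotated by angle_deg about +x."""
    topo1, cfg1, pairs1 = synthetic.build_duplex(synthetic.HelixSpec(n_bp=n_bp))
    n = topo1.n_nucleotides
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.array([1.0, 0.0, 0.0]))
    rm = rot.as_matrix()
    nts = list(topo1.nucleotides)
    for nt in topo1.nucleotides:
        nts.append(
            Nucleotide(
                global_id=nt.global_id + n,
                strand_id=nt.strand_id + 2,
                base=nt.base,
                neighbor_3=None if nt.neighbor_3 is None else nt.neighbor_3 + n,
                neighbor_5=None if nt.neighbor_5 is None else nt.neighbor_5 + n,
            )
        )
    topo = Topology(nts)
    cfg = Configuration(
        time=0.0,
        box=np.full(3, 100.0),
        energies=np.zeros(3),
        positions=np.vstack([cfg1.positions, cfg1.positions @ rm.T + np.asarray(offset)]),
        a1=np.vstack([cfg1.a1, cfg1.a1 @ rm.T]),
        a3=np.vstack([cfg1.a3, cfg1.a3 @ rm.T]),
    )
    pairs = DesignedPairs(
        list(pairs1.pairs) + [(i + n, j + n) for i, j in pairs1.pairs]
    )
    return topo, cfg, pairs


@pytest.fixture
def two_duplex_60():
    return make_two_duplex_fixture(60.0)


def random_rotation(rng) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
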