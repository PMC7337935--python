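"""Shared fixture writer for rigid-body relaxation CLI tests."""

import numpy as np

from oxtraj.core import Configuration, Nucleotide, Topology
from oxtraj.io_oxdna import write_topology, write_trajectory


def write_two_blob_fixture(tmp_path):
    """One 8-nt strand whose two 4-particle halves sit 6 units apart."""
    offsets = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    pos = np.vstack([offsets, offsets + np.array([6.0, 0, 0])])
    cfg = Configuration(
        time=0.0,
        box=np.full(3, 100.0),
        energies=np.zeros(3),
        positions=pos,
        a1=np.tile([1.0, 0.0, 0.0], (8, 1)),
        a3=np.tile([0.0, 0.0, 1.0], (8, 1)),
    )
    nts = [
        Nucleotide(
            global_id=i,
            strand_id=1,
            base="A",
            neighbor_3=i - 1 if i > 0 else None,
            neighbor_5=i + 1 if i < 7 else None,
        )
        for i in range(8)
    ]
    topo = Topology(nts)
    top = tmp_path / "blob.top"
    conf = tmp_path / "blob.dat"
    write_topology(topo, top)
    write_trajectory([cfg], conf)
    return str(top), str(conf)
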