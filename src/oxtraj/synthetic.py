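"""Synthetic topologies and trajectories with known ground truth.

These generators make every analysis testable without running a simulator:
ideal A-/B-form duplexes, gapped duplexes, Gaussian-perturbed trajectories,
trajectories with a planted collective motion mode, and two-state mixtures.
All generators are pure functions of their arguments (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    Configuration,
    InMemoryTrajectory,
    Nucleotide,
    Topology,
    orthonormalize_pair,
)
from .io_oxdna import DesignedPairs

# canonical helix parameters, simulation length units
B_FORM_RISE = 0.3897  # ~0.34 nm
B_FORM_TWIST = 34.3  # degrees per bp
A_FORM_RISE = 0.3287  # ~0.28 nm
A_FORM_TWIST = 32.7
BACKBONE_RADIUS = 0.6
#: radial displacement of A-form base-pair midpoints off the helix axis
A_FORM_MIDPOINT_SHIFT = 0.25

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}


@dataclass
class HelixSpec:
    n_bp: int
    form: str = "B"
    rise: Optional[float] = None
    twist: Optional[float] = None
    radius: float = BACKBONE_RADIUS
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.form not in ("A", "B"):
            raise ValueError(f"form must be 'A' or 'B', got {self.form!r}")
        if self.rise is None:
            self.rise = B_FORM_RISE if self.form == "B" else A_FORM_RISE
        if self.twist is None:
            self.twist = B_FORM_TWIST if self.form == "B" else A_FORM_TWIST
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360) degrees")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_bp:
            raise ValueError(
                f"sequence length {len(self.sequence)} != n_bp {self.n_bp}"
            )


@dataclass
class NoiseSpec:
    sigma: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _duplex_geometry(spec: HelixSpec, n_bp: int, z0: float = 0.0, phase0: float = 0.0):
    """Per-bp midpoints, radial unit vectors and z heights for one duplex run."""
    k = np.arange(n_bp)
    theta = np.deg2rad(spec.twist) * k + phase0
    u = np.stack([np.cos(theta), np.sin(theta), np.zeros(n_bp)], axis=1)
    z = z0 + spec.rise * k
    shift = A_FORM_MIDPOINT_SHIFT if spec.form == "A" else 0.0
    mid = shift * u + np.stack([np.zeros(n_bp), np.zeros(n_bp), z], axis=1)
    return mid, u


def build_duplex(spec: HelixSpec) -> tuple[Topology, Configuration, DesignedPairs]:
    """Ideal antiparallel duplex along +z; bp i of strand 1 pairs with bp
    (n_bp - 1 - i) of strand 2 (global ids n_bp .. 2*n_bp - 1)."""
    n = spec.n_bp
    seq = spec.sequence or ("ATGC" * (n // 4 + 1))[:n]
    mid, u = _duplex_geometry(spec, n)

    pos = np.empty((2 * n, 3))
    a1 = np.empty((2 * n, 3))
    a3 = np.empty((2 * n, 3))
    # strand 1: backbone outward along +u, base pointing inward
    pos[:n] = mid + spec.radius * u
    a1[:n] = -u
    a3[:n] = np.array([0.0, 0.0, 1.0])
    # strand 2 nucleotide (n + j) pairs with strand-1 nucleotide (n - 1 - j)
    j = np.arange(n)
    part = n - 1 - j
    pos[n:] = mid[part] - spec.radius * u[part]
    a1[n:] = u[part]
    a3[n:] = np.array([0.0, 0.0, -1.0])

    nts = []
    for i in range(n):  # strand 1 stored 3'->5'
        nts.append(
            Nucleotide(
                global_id=i,
                strand_id=1,
                base=seq[i],
                neighbor_3=i - 1 if i > 0 else None,
                neighbor_5=i + 1 if i < n - 1 else None,
            )
        )
    for jj in range(n):
        gid = n + jj
        nts.append(
            Nucleotide(
                global_id=gid,
                strand_id=2,
                base=_COMPLEMENT.get(seq[n - 1 - jj], "A"),
                neighbor_3=gid - 1 if jj > 0 else None,
                neighbor_5=gid + 1 if jj < n - 1 else None,
            )
        )
    topo = Topology(nts)
    config = Configuration(
        time=0.0,
        box=np.full(3, max(20.0, 3 * n * spec.rise)),
        energies=np.zeros(3),
        positions=pos,
        a1=a1,
        a3=a3,
    )
    config.validate(topo.n_nucleotides)
    pairs = DesignedPairs((i, 2 * n - 1 - i) for i in range(n))
    return topo, config, pairs


def build_interrupted_duplex(
    segment_bps: Sequence[int], gap_nt: int, spec: Optional[HelixSpec] = None
) -> tuple[Topology, Configuration, DesignedPairs]:
    """Duplex segments joined by single-stranded gaps on one strand.

    Strand 1 runs the whole length (segments + gaps); each segment gets its
    own complementary strand on the other side.  Designed pairs cover only
    the duplexed bases, so the unpaired count equals gap_nt * (n_segments-1).
    """
    if any(s <= 0 for s in segment_bps):
        raise ValueError("segment lengths must be positive")
    if gap_nt < 0:
        raise ValueError("gap_nt must be >= 0")
    segment_bps = list(segment_bps)
    total1 = sum(segment_bps) + gap_nt * (len(segment_bps) - 1)
    base = spec or HelixSpec(n_bp=total1)
    full = HelixSpec(
        n_bp=total1, form=base.form, rise=base.rise, twist=base.twist,
        radius=base.radius,
    )
    seq = ("ATGC" * (total1 // 4 + 1))[:total1]
    mid, u = _duplex_geometry(full, total1)

    # strand 1: continuous
    pos1 = mid + full.radius * u
    nts = [
        Nucleotide(
            global_id=i,
            strand_id=1,
            base=seq[i],
            neighbor_3=i - 1 if i > 0 else None,
            neighbor_5=i + 1 if i < total1 - 1 else None,
        )
        for i in range(total1)
    ]
    pos_rows = [pos1]
    a1_rows = [-u]
    a3_rows = [np.tile([0.0, 0.0, 1.0], (total1, 1))]

    pair_list: list[tuple[int, int]] = []
    gid = total1
    start = 0
    for s_idx, seg in enumerate(segment_bps):
        idx1 = np.arange(start, start + seg)  # strand-1 ids in this segment
        comp_order = idx1[::-1]  # antiparallel partner order
        seg_ids = []
        for jj, i1 in enumerate(comp_order):
            nts.append(
                Nucleotide(
                    global_id=gid,
                    strand_id=2 + s_idx,
                    base=_COMPLEMENT.get(seq[i1], "A"),
                    neighbor_3=gid - 1 if jj > 0 else None,
                    neighbor_5=gid + 1 if jj < seg - 1 else None,
                )
            )
            pair_list.append((i1, gid))
            seg_ids.append(gid)
            gid += 1
        pos_rows.append(mid[comp_order] - full.radius * u[comp_order])
        a1_rows.append(u[comp_order])
        a3_rows.append(np.tile([0.0, 0.0, -1.0], (seg, 1)))
        start += seg + gap_nt

    topo = Topology(nts)
    config = Configuration(
        time=0.0,
        box=np.full(3, max(20.0, 3 * total1 * full.rise)),
        energies=np.zeros(3),
        positions=np.vstack(pos_rows),
        a1=np.vstack(a1_rows),
        a3=np.vstack(a3_rows),
    )
    config.validate(topo.n_nucleotides)
    return topo, config, DesignedPairs(pair_list)


def _rotate_versors(
    a1: np.ndarray, a3: np.ndarray, angles: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    axes = rng.normal(size=a1.shape)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    rot = Rotation.from_rotvec(axes * angles[:, None])
    return orthonormalize_pair(rot.apply(a1), rot.apply(a3))


def perturb(
    config: Configuration,
    noise: NoiseSpec,
    topology: Optional[Topology] = None,
    rise: float = B_FORM_RISE,
) -> InMemoryTrajectory:
    """iid Gaussian positional noise plus commensurate orientational noise."""
    rng = np.random.default_rng(noise.seed)
    frames = []
    ang_sigma = noise.sigma / rise
    for f in range(noise.n_frames):
        c = config.copy()
        c.time = float(f)
        if noise.sigma > 0:
            c.positions = c.positions + rng.normal(
                scale=noise.sigma, size=c.positions.shape
            )
            angles = rng.normal(scale=ang_sigma, size=c.n)
            c.a1, c.a3 = _rotate_versors(c.a1, c.a3, angles, rng)
        frames.append(c)
    topo = topology if topology is not None else _point_topology(config.n)
    return InMemoryTrajectory(topo, frames)


def planted_mode_trajectory(
    config: Configuration,
    mode: np.ndarray,
    amp_std: float,
    noise_sigma: float,
    n_frames: int,
    seed: int = 0,
    topology: Optional[Topology] = None,
) -> InMemoryTrajectory:
    """frame f = config + c_f * mode + iid noise, with c_f ~ N(0, amp_std^2).

    ``mode`` is an (N, 3) field normalized to unit Frobenius norm internally.
    """
    mode = np.asarray(mode, dtype=float).reshape(config.n, 3)
    mode = mode / np.linalg.norm(mode)
    rng = np.random.default_rng(seed)
    amps = rng.normal(scale=amp_std, size=n_frames)
    frames = []
    for f in range(n_frames):
        c = config.copy()
        c.time = float(f)
        c.positions = c.positions + amps[f] * mode
        if noise_sigma > 0:
            c.positions = c.positions + rng.normal(
                scale=noise_sigma, size=c.positions.shape
            )
        frames.append(c)
    topo = topology if topology is not None else _point_topology(config.n)
    return InMemoryTrajectory(topo, frames)


def two_state_trajectory(
    config_a: Configuration,
    config_b: Configuration,
    frac_a: float,
    noise_sigma: float,
    n_frames: int,
    seed: int = 0,
    topology: Optional[Topology] = None,
) -> tuple[InMemoryTrajectory, np.ndarray]:
    """Frames drawn from state A (probability frac_a) or B, plus noise.

    Returns the trajectory and the true per-frame labels (0 = A, 1 = B).
    """
    if config_a.n != config_b.n:
        raise ValueError("states must have the same particle count")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_frames) >= frac_a).astype(int)
    frames = []
    for f in range(n_frames):
        src = config_b if labels[f] else config_a
        c = src.copy()
        c.time = float(f)
        if noise_sigma > 0:
            c.positions = c.positions + rng.normal(
                scale=noise_sigma, size=c.positions.shape
            )
        frames.append(c)
    topo = topology if topology is not None else _point_topology(config_a.n)
    return InMemoryTrajectory(topo, frames), labels


def orthogonalize_to_rigid(config: Configuration, mode: np.ndarray) -> np.ndarray:
    """Project the 3 translational and 3 infinitesimal-rotational components
    out of a displacement field and renormalize.

    Planted modes built this way survive rigid alignment unchanged, which is
    what makes single-mode recovery exact.
    """
    n = config.n
    mode = np.asarray(mode, dtype=float).reshape(n, 3)
    x = config.positions - config.positions.mean(axis=0)
    rigid = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        rigid.append(t.ravel())
    for k in range(3):
        ax = np.zeros(3)
        ax[k] = 1.0
        rigid.append(np.cross(np.tile(ax, (n, 1)), x).ravel())
    q, _ = np.linalg.qr(np.array(rigid).T)
    flat = mode.ravel()
    flat = flat - q @ (q.T @ flat)
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise ValueError("mode is entirely rigid-body motion")
    return (flat / norm).reshape(n, 3)


def bent_copy(config: Configuration, angle_deg: float, axis=(1.0, 0.0, 0.0)) -> Configuration:
    """Second conformational state: rotate the upper half (by z) of the
    structure about the centroid.  A genuine shape change, not removable by
    rigid alignment."""
    out = config.copy()
    z_mid = np.median(config.positions[:, 2])
    sel = config.positions[:, 2] > z_mid
    pivot = config.positions[sel].min(axis=0)
    rot = Rotation.from_rotvec(
        np.deg2rad(angle_deg) * np.asarray(axis, dtype=float)
    ).as_matrix()
    out.positions[sel] = (config.positions[sel] - pivot) @ rot.T + pivot
    out.a1[sel] = config.a1[sel] @ rot.T
    out.a3[sel] = config.a3[sel] @ rot.T
    return out


def _point_topology(n: int) -> Topology:
    """Placeholder topology of n unlinked single-nucleotide strands."""
    return Topology(
        [Nucleotide(global_id=i, strand_id=i + 1, base="A") for i in range(n)]
    )


__all__ = [
    "HelixSpec",
    "NoiseSpec",
    "B_FORM_RISE",
    "B_FORM_TWIST",
    "A_FORM_RISE",
    "A_FORM_TWIST",
    "BACKBONE_RADIUS",
    "build_duplex",
    "build_interrupted_duplex",
    "perturb",
    "planted_mode_trajectory",
    "two_state_trajectory",
    "orthogonalize_to_rigid",
    "bent_copy",
]
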