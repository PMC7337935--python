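"""SVD-based rigid superposition, trajectory alignment, mean structure,
per-nucleotide RMSF and centroid extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    NM_PER_UNIT,
    Configuration,
    InMemoryTrajectory,
    Trajectory,
    orthonormalize_pair,
)
from .io_oxdna import ColorOverlay
from . import parallel as _par


class DegenerateFitError(ValueError):
    """Raised when the fitting subset cannot determine a unique rotation."""


@dataclass
class RigidTransform:
    """Proper rotation (det = +1) followed by a translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return vectors @ self.rotation.T

    def validate(self) -> None:
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-10):
            raise ValueError("rotation is not proper (det != +1)")


@dataclass
class MeanStructureResult:
    mean: Configuration
    reference_index: int
    subset: Optional[list[int]]


@dataclass
class RMSFProfile:
    """Per-nucleotide root-mean-square fluctuation, in nanometres."""

    values_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if (self.values_nm < 0).any():
            raise ValueError("RMSF values must be non-negative")


def kabsch_fit(
    mobile: np.ndarray,
    target: np.ndarray,
    subset: Optional[Sequence[int]] = None,
) -> RigidTransform:
    """Least-RMSD rigid transform taking ``mobile`` onto ``target``.

    The fit uses only ``subset`` rows when given; reflections are corrected
    so the returned rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    idx = np.arange(mobile.shape[0]) if subset is None else np.asarray(subset)
    p = mobile[idx]
    q = target[idx]
    if p.shape[0] < 3:
        raise DegenerateFitError(f"need >= 3 fitting points, got {p.shape[0]}")
    pc = p - p.mean(axis=0)
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-300):
        raise DegenerateFitError("fitting subset is collinear")
    pm, qm = p.mean(axis=0), q.mean(axis=0)
    h = (p - pm).T @ (q - qm)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=qm - rot @ pm)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _transform_config(config: Configuration, tf: RigidTransform) -> Configuration:
    out = config.copy()
    out.positions = tf.apply(config.positions)
    out.a1 = tf.apply_vectors(config.a1)
    out.a3 = tf.apply_vectors(config.a3)
    return out


def align_config(
    config: Configuration,
    reference: Configuration,
    subset: Optional[Sequence[int]] = None,
) -> Configuration:
    tf = kabsch_fit(config.positions, reference.positions, subset)
    return _transform_config(config, tf)


def align_trajectory(
    traj: Trajectory,
    reference: Union[int, Configuration] = 0,
    subset: Optional[Sequence[int]] = None,
) -> InMemoryTrajectory:
    """Rigid-fit every frame onto the reference; the subset controls the fit
    but the transform is applied to all particles (positions and versors)."""
    ref = traj[reference] if isinstance(reference, int) else reference
    if ref.n != traj.topology.n_nucleotides:
        raise ValueError("reference incompatible with trajectory topology")
    frames = [align_config(c, ref, subset) for c in traj]
    return InMemoryTrajectory(traj.topology, frames)


def mean_structure(
    traj: Trajectory,
    reference: Union[int, Configuration] = 0,
    subset: Optional[Sequence[int]] = None,
) -> MeanStructureResult:
    """Arithmetic mean of aligned positions; mean versors are re-orthonormalized
    (a3 normalized first, then a1 projected orthogonal)."""
    if len(traj) < 1:
        raise ValueError("mean_structure needs at least one frame")
    ref_index = reference if isinstance(reference, int) else -1
    ref = traj[reference] if isinstance(reference, int) else reference
    aligned = align_trajectory(traj, ref, subset)
    pos = np.mean([c.positions for c in aligned], axis=0)
    a1 = np.mean([c.a1 for c in aligned], axis=0)
    a3 = np.mean([c.a3 for c in aligned], axis=0)
    a1, a3 = orthonormalize_pair(a1, a3)
    mean = Configuration(
        time=0.0,
        box=ref.box.copy(),
        energies=np.zeros(3),
        positions=pos,
        a1=a1,
        a3=a3,
    )
    return MeanStructureResult(
        mean=mean,
        reference_index=ref_index,
        subset=None if subset is None else list(subset),
    )


def _rmsf_chunk(traj, start, stop, mean_pos, subset):
    sq = np.zeros(mean_pos.shape[0])
    for k in range(start, stop):
        c = traj[k]
        tf = kabsch_fit(c.positions, mean_pos, subset)
        d = tf.apply(c.positions) - mean_pos
        sq += np.sum(d * d, axis=1)
    return sq, stop - start


def rmsf(
    traj: Trajectory,
    mean: MeanStructureResult,
    n_cpus: int = 1,
) -> tuple[RMSFProfile, ColorOverlay]:
    """RMSF_i = sqrt(mean_f |x_i,f - mean_i|^2), reported in nanometres."""
    mean_pos = mean.mean.positions
    if mean_pos.shape[0] != traj.topology.n_nucleotides:
        raise ValueError("mean structure incompatible with trajectory")
    partials = _par.parallel_map(
        traj, _rmsf_chunk, n_cpus, args=(mean_pos, mean.subset)
    )
    sq = np.sum([p[0] for p in partials], axis=0)
    count = sum(p[1] for p in partials)
    values = np.sqrt(sq / count) * NM_PER_UNIT
    profile = RMSFProfile(values_nm=values)
    return profile, ColorOverlay(name="RMSF (nm)", values=values)


def centroid(
    traj: Trajectory,
    reference: Union[int, Configuration],
    subset: Optional[Sequence[int]] = None,
) -> tuple[int, Configuration]:
    """Frame with the lowest post-alignment RMSD to the reference.

    Ties are broken by the lowest frame index.
    """
    ref = traj[reference] if isinstance(reference, int) else reference
    best_k, best_val, best_cfg = -1, np.inf, None
    for k in range(len(traj)):
        cfg = align_config(traj[k], ref, subset)
        val = rmsd(cfg.positions, ref.positions)
        if val < best_val - 1e-15:
            best_k, best_val, best_cfg = k, val, cfg
    return best_k, best_cfg


def superimpose_configs(
    configs: Sequence[Configuration],
    subset: Optional[Sequence[int]] = None,
) -> list[Configuration]:
    """Align every configuration onto the first; the first is returned as-is."""
    if not configs:
        return []
    n0 = configs[0].n
    for c in configs[1:]:
        if c.n != n0:
            raise ValueError("configurations differ in particle count")
    out = [configs[0]]
    out.extend(align_config(c, configs[0], subset) for c in configs[1:])
    return out


__all__ = [
    "DegenerateFitError",
    "RigidTransform",
    "MeanStructureResult",
    "RMSFProfile",
    "kabsch_fit",
    "rmsd",
    "align_config",
    "align_trajectory",
    "mean_structure",
    "rmsf",
    "centroid",
    "superimpose_configs",
]
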