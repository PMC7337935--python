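"""Rigid-body relaxation of multi-component structures.

Nucleotides are partitioned into rigid groups (via DBSCAN on positions or
user index lists).  Groups are pulled together by springs at inter-group
backbone bonds, f_spr = c_spr * (l - l_r), and pushed apart by a linear
centre-to-centre repulsion, f_rep = max(c_rep * (1 - d / (r_a + r_b)), 0).
Damped first-order rigid updates (net force translates, spring torque
rotates) run until the largest per-group net force falls below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Configuration, Topology, orthonormalize_pair
from .clustering import dbscan


class DivergenceError(RuntimeError):
    pass


@dataclass
class RigidGroup:
    members: np.ndarray  # global ids
    center: np.ndarray  # current centre of mass
    rotation: np.ndarray  # orientation relative to the initial pose
    offsets: np.ndarray  # member offsets from the centre, initial body frame
    radius: float

    @classmethod
    def from_config(cls, config: Configuration, members: Sequence[int]) -> "RigidGroup":
        members = np.asarray(sorted(members), dtype=int)
        pos = config.positions[members]
        center = pos.mean(axis=0)
        offsets = pos - center
        radius = float(np.linalg.norm(offsets, axis=1).max(initial=0.0))
        return cls(
            members=members,
            center=center,
            rotation=np.eye(3),
            offsets=offsets,
            radius=radius,
        )

    def positions(self) -> np.ndarray:
        return self.center + self.offsets @ self.rotation.T

    def position_of(self, global_id: int) -> np.ndarray:
        idx = int(np.searchsorted(self.members, global_id))
        if idx >= len(self.members) or self.members[idx] != global_id:
            raise KeyError(f"nucleotide {global_id} not in group")
        return self.center + self.rotation @ self.offsets[idx]


@dataclass
class RelaxParams:
    c_spr: float = 1.0
    l_r: float = 0.76  # relaxed backbone bond length, simulation units
    c_rep: float = 10.0
    damping: float = 0.95
    step: float = 0.05
    max_iter: int = 100_000
    force_tol: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("c_spr", "l_r", "c_rep", "step", "force_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    max_force: float
    energy_trace: list[float] = field(default_factory=list)


def identify_groups(
    config: Configuration, eps: float, min_size: int
) -> list[RigidGroup]:
    """DBSCAN over positions; noise particles become singleton groups so
    every nucleotide can still move."""
    assignment = dbscan(config.positions, eps=eps, min_samples=min_size)
    groups = []
    for lab in range(assignment.n_clusters):
        groups.append(RigidGroup.from_config(config, assignment.members(lab)))
    for k in assignment.members(-1):
        groups.append(RigidGroup.from_config(config, [int(k)]))
    return groups


def inter_group_springs(
    topology: Topology, groups: Sequence[RigidGroup]
) -> list[tuple[int, int, int, int]]:
    """(group_a, group_b, nucleotide_in_a, nucleotide_in_b) for every backbone
    bond whose endpoints lie in different groups."""
    owner: dict[int, int] = {}
    for g_idx, g in enumerate(groups):
        for m in g.members:
            if int(m) in owner:
                raise ValueError(f"nucleotide {m} assigned to two groups")
            owner[int(m)] = g_idx
    springs = []
    for i, j in topology.backbone_bonds():
        gi, gj = owner.get(i), owner.get(j)
        if gi is None or gj is None or gi == gj:
            continue
        springs.append((gi, gj, i, j))
    return springs


def spring_force(l: float, params: RelaxParams) -> float:
    """Signed magnitude along the inter-attachment direction: positive pulls
    the attachment points together, negative (l < l_r) pushes apart."""
    return params.c_spr * (l - params.l_r)


def repulsion_force(d: float, r_a: float, r_b: float, params: RelaxParams) -> float:
    """Linear overlap repulsion, zero at and beyond contact (d >= r_a + r_b)."""
    return max(params.c_rep * (1.0 - d / (r_a + r_b)), 0.0)


def _potential_energy(
    groups: Sequence[RigidGroup],
    springs: Sequence[tuple[int, int, int, int]],
    params: RelaxParams,
) -> float:
    e = 0.0
    for ga, gb, i, j in springs:
        l = float(
            np.linalg.norm(groups[ga].position_of(i) - groups[gb].position_of(j))
        )
        e += 0.5 * params.c_spr * (l - params.l_r) ** 2
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rsum = groups[a].radius + groups[b].radius
            if rsum == 0:
                continue
            d = float(np.linalg.norm(groups[a].center - groups[b].center))
            if d < rsum:
                # integral of the linear force from d to contact
                e += 0.5 * params.c_rep * rsum * (1.0 - d / rsum) ** 2
    return e


def relax(
    config: Configuration,
    groups: Sequence[RigidGroup],
    params: Optional[RelaxParams] = None,
    topology: Optional[Topology] = None,
    springs: Optional[Sequence[tuple[int, int, int, int]]] = None,
    pinned: Sequence[int] = (),
) -> tuple[Configuration, ConvergenceReport]:
    """Damped rigid-body relaxation; returns the updated configuration and a
    convergence report.  Members of ``pinned`` groups never move.

    Raises :class:`DivergenceError` if the potential energy increases for
    100 consecutive checkpoints.
    """
    params = params or RelaxParams()
    if springs is None:
        if topology is None:
            raise ValueError("provide either precomputed springs or a topology")
        springs = inter_group_springs(topology, groups)
    groups = [
        RigidGroup(
            members=g.members.copy(),
            center=g.center.copy(),
            rotation=g.rotation.copy(),
            offsets=g.offsets.copy(),
            radius=g.radius,
        )
        for g in groups
    ]
    pinned_set = set(pinned)
    n_groups = len(groups)
    vel = np.zeros((n_groups, 3))
    avel = np.zeros((n_groups, 3))
    report = ConvergenceReport(converged=False, iterations=0, max_force=np.inf)
    rising = 0
    prev_energy = _potential_energy(groups, springs, params)
    report.energy_trace.append(prev_energy)

    for it in range(1, params.max_iter + 1):
        forces = np.zeros((n_groups, 3))
        torques = np.zeros((n_groups, 3))
        for ga, gb, i, j in springs:
            pa = groups[ga].position_of(i)
            pb = groups[gb].position_of(j)
            dvec = pb - pa
            l = float(np.linalg.norm(dvec))
            if l < 1e-12:
                continue
            f = spring_force(l, params) * dvec / l  # force on attachment a
            forces[ga] += f
            forces[gb] -= f
            torques[ga] += np.cross(pa - groups[ga].center, f)
            torques[gb] += np.cross(pb - groups[gb].center, -f)
        for a in range(n_groups):
            for b in range(a + 1, n_groups):
                rsum = groups[a].radius + groups[b].radius
                if rsum == 0:
                    continue
                dvec = groups[a].center - groups[b].center
                d = float(np.linalg.norm(dvec))
                mag = repulsion_force(d, groups[a].radius, groups[b].radius, params)
                if mag <= 0:
                    continue
                direction = dvec / d if d > 1e-12 else np.array([1.0, 0.0, 0.0])
                forces[a] += mag * direction
                forces[b] -= mag * direction
        for g_idx in pinned_set:
            forces[g_idx] = 0.0
            torques[g_idx] = 0.0

        max_force = float(np.linalg.norm(forces, axis=1).max(initial=0.0))
        report.iterations = it
        report.max_force = max_force
        # require residual momentum to have decayed too, so groups coast to
        # rest past the zero-force boundary instead of stopping on it
        max_vel = float(np.linalg.norm(vel, axis=1).max(initial=0.0))
        if max_force < params.force_tol and max_vel < params.step * params.force_tol:
            report.converged = True
            break

        vel = params.damping * vel + params.step * forces
        avel = params.damping * avel + params.step * torques
        for g_idx, g in enumerate(groups):
            if g_idx in pinned_set:
                continue
            g.center = g.center + vel[g_idx]
            angle = float(np.linalg.norm(avel[g_idx]))
            if angle > 1e-15:
                rot = Rotation.from_rotvec(avel[g_idx]).as_matrix()
                g.rotation = rot @ g.rotation

        if it % 50 == 0:
            energy = _potential_energy(groups, springs, params)
            report.energy_trace.append(energy)
            if not np.isfinite(energy):
                raise DivergenceError(
                    f"potential energy became non-finite at iteration {it}"
                )
            if energy > prev_energy + 1e-12:
                rising += 1
                if rising >= 100:
                    raise DivergenceError(
                        f"energy increased for {rising} consecutive checkpoints "
                        f"(iteration {it}, energy {energy:.6g})"
                    )
            else:
                rising = 0
            prev_energy = energy

    out = config.copy()
    for g in groups:
        out.positions[g.members] = g.positions()
        out.a1[g.members] = out.a1[g.members] @ g.rotation.T
        out.a3[g.members] = out.a3[g.members] @ g.rotation.T
    out.a1, out.a3 = orthonormalize_pair(out.a1, out.a3)
    return out, report


__all__ = [
    "RigidGroup",
    "RelaxParams",
    "ConvergenceReport",
    "DivergenceError",
    "identify_groups",
    "inter_group_springs",
    "spring_force",
    "repulsion_force",
    "relax",
]
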