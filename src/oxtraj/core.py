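"""Domain types and unit conventions shared by every analysis.

The model represents each nucleotide as a single rigid body carrying a
centre-of-mass position and two orientation versors: ``a1`` points from
the backbone toward the base interaction site, ``a3`` along the stacking
axis.  Internal math is done in simulation length units; user-facing
distances are converted to nanometres with :data:`NM_PER_UNIT`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

#: backbone -> base-site offset along a1, simulation length units (DNA model)
POS_BASE = 0.4

#: nanometres per simulation length unit
NM_PER_UNIT = 0.8518

#: tolerance for versor unit-norm checks
_NORM_TOL = 1e-5
#: tolerance for a1.a3 orthogonality checks
_ORTHO_TOL = 1e-4


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class Nucleotide:
    """One monomer: identity, strand membership and backbone connectivity."""

    global_id: int
    strand_id: int
    base: str
    neighbor_3: Optional[int] = None
    neighbor_5: Optional[int] = None

    def __post_init__(self) -> None:
        if self.neighbor_3 == self.global_id or self.neighbor_5 == self.global_id:
            raise ValidationError(
                f"nucleotide {self.global_id} cannot neighbor itself"
            )


class Topology:
    """Strand/nucleotide identity and 3'-5' connectivity shared by all frames."""

    def __init__(self, nucleotides: Sequence[Nucleotide]):
        self.nucleotides: list[Nucleotide] = list(nucleotides)
        self._strands: dict[int, list[int]] = {}
        for nt in self.nucleotides:
            self._strands.setdefault(nt.strand_id, []).append(nt.global_id)
        self._circular: dict[int, bool] = {}
        self._validate()

    @property
    def n_nucleotides(self) -> int:
        return len(self.nucleotides)

    @property
    def n_strands(self) -> int:
        return len(self._strands)

    @property
    def strand_ids(self) -> list[int]:
        return sorted(self._strands)

    def strand_members(self, strand_id: int) -> list[int]:
        """Global ids of a strand's nucleotides, in file order."""
        return list(self._strands[strand_id])

    def is_circular(self, strand_id: int) -> bool:
        return self._circular[strand_id]

    def backbone_bonds(self) -> list[tuple[int, int]]:
        """Each backbone bond once, as an (i, j) tuple with i < j."""
        bonds = set()
        for nt in self.nucleotides:
            for nb in (nt.neighbor_3, nt.neighbor_5):
                if nb is not None:
                    bonds.add((min(nt.global_id, nb), max(nt.global_id, nb)))
        return sorted(bonds)

    def strand_sequence_5to3(self, strand_id: int) -> str:
        """Sequence read 5'->3'.  Circular strands start at the lowest id."""
        ids = self.five_to_three_order(strand_id)
        return "".join(self.nucleotides[i].base for i in ids)

    def five_to_three_order(self, strand_id: int) -> list[int]:
        members = set(self._strands[strand_id])
        if self._circular[strand_id]:
            start = min(members)
        else:
            ends = [i for i in members if self.nucleotides[i].neighbor_5 is None]
            start = ends[0]
        order = [start]
        cur = start
        while True:
            nxt = self.nucleotides[cur].neighbor_3
            if nxt is None or nxt == start:
                break
            order.append(nxt)
            cur = nxt
        return order

    def _validate(self) -> None:
        n = self.n_nucleotides
        for i, nt in enumerate(self.nucleotides):
            if nt.global_id != i:
                raise ValidationError(
                    f"nucleotide at index {i} has global_id {nt.global_id}"
                )
            for nb in (nt.neighbor_3, nt.neighbor_5):
                if nb is not None and not (0 <= nb < n):
                    raise ValidationError(
                        f"nucleotide {i} references out-of-range neighbor {nb}"
                    )
        # mutual links
        for nt in self.nucleotides:
            if nt.neighbor_3 is not None:
                other = self.nucleotides[nt.neighbor_3]
                if other.neighbor_5 != nt.global_id:
                    raise ValidationError(
                        f"asymmetric connectivity: {nt.global_id} -> 3' "
                        f"{nt.neighbor_3} is not reciprocated"
                    )
            if nt.neighbor_5 is not None:
                other = self.nucleotides[nt.neighbor_5]
                if other.neighbor_3 != nt.global_id:
                    raise ValidationError(
                        f"asymmetric connectivity: {nt.global_id} -> 5' "
                        f"{nt.neighbor_5} is not reciprocated"
                    )
            for nb in (nt.neighbor_3, nt.neighbor_5):
                if nb is not None:
                    if self.nucleotides[nb].strand_id != nt.strand_id:
                        raise ValidationError(
                            f"bond {nt.global_id}-{nb} crosses strands"
                        )
        # each strand is a single path or single cycle
        for sid, members in self._strands.items():
            mset = set(members)
            ends = [
                i
                for i in members
                if self.nucleotides[i].neighbor_5 is None
                or self.nucleotides[i].neighbor_3 is None
            ]
            if not ends:  # candidate cycle
                circular = True
                start = members[0]
            else:
                circular = False
                starts = [
                    i for i in members if self.nucleotides[i].neighbor_5 is None
                ]
                if len(starts) != 1:
                    raise ValidationError(
                        f"strand {sid} does not form a single path"
                    )
                start = starts[0]
            seen = {start}
            cur = start
            while True:
                nxt = self.nucleotides[cur].neighbor_3
                if nxt is None or nxt == start:
                    break
                if nxt in seen or nxt not in mset:
                    raise ValidationError(
                        f"strand {sid} connectivity is not a single "
                        f"{'cycle' if circular else 'path'}"
                    )
                seen.add(nxt)
                cur = nxt
            if seen != mset:
                raise ValidationError(
                    f"strand {sid} is disconnected ({len(seen)} of "
                    f"{len(mset)} reachable)"
                )
            self._circular[sid] = circular


@dataclass
class Configuration:
    """One frame: positions plus (a1, a3) orientation versors for N particles."""

    time: float
    box: np.ndarray
    energies: np.ndarray
    positions: np.ndarray
    a1: np.ndarray
    a3: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a3 = np.asarray(self.a3, dtype=float)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def a2(self) -> np.ndarray:
        """Third body axis, computed on demand as a3 x a1."""
        return np.cross(self.a3, self.a1)

    def copy(self) -> "Configuration":
        return Configuration(
            time=self.time,
            box=self.box.copy(),
            energies=self.energies.copy(),
            positions=self.positions.copy(),
            a1=self.a1.copy(),
            a3=self.a3.copy(),
        )

    def validate(self, n_expected: Optional[int] = None) -> None:
        n = self.positions.shape[0]
        if n_expected is not None and n != n_expected:
            raise ValidationError(
                f"configuration has {n} particles, expected {n_expected}"
            )
        for name, arr in (("positions", self.positions), ("a1", self.a1), ("a3", self.a3)):
            if arr.shape != (n, 3):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({n}, 3)")
        for name, arr in (("a1", self.a1), ("a3", self.a3)):
            norms = np.linalg.norm(arr, axis=1)
            worst = np.abs(norms - 1.0).max(initial=0.0)
            if worst > _NORM_TOL:
                raise ValidationError(
                    f"{name} versors deviate from unit norm by {worst:.2e}"
                )
        dots = np.abs(np.einsum("ij,ij->i", self.a1, self.a3))
        if dots.max(initial=0.0) > _ORTHO_TOL:
            raise ValidationError(
                f"a1/a3 orthogonality violated by {dots.max():.2e}"
            )


def base_site_position(
    config: Configuration, i: int, pos_base: float = POS_BASE
) -> np.ndarray:
    """Position of the base interaction site of nucleotide ``i``."""
    if not 0 <= i < config.n:
        raise IndexError(f"nucleotide id {i} out of range [0, {config.n})")
    return config.positions[i] + pos_base * config.a1[i]


def base_site_positions(
    config: Configuration, pos_base: float = POS_BASE
) -> np.ndarray:
    """Base-site positions of all nucleotides, shape (N, 3)."""
    return config.positions + pos_base * config.a1


class Trajectory:
    """Ordered configurations over one topology, addressable by frame index."""

    topology: Topology

    def __len__(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def __getitem__(self, k: int) -> Configuration:  # pragma: no cover
        raise NotImplementedError

    def __iter__(self) -> Iterator[Configuration]:
        for k in range(len(self)):
            yield self[k]

    @property
    def frame_count(self) -> int:
        return len(self)


class InMemoryTrajectory(Trajectory):
    def __init__(self, topology: Topology, frames: Sequence[Configuration]):
        self.topology = topology
        self.frames = list(frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> Configuration:
        return self.frames[k]


def orthonormalize_pair(a1: np.ndarray, a3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gram-Schmidt: normalize a3 first, then project it out of a1.

    Operates row-wise on (N, 3) arrays.
    """
    a3n = a3 / np.linalg.norm(a3, axis=-1, keepdims=True)
    a1p = a1 - np.einsum("...i,...i->...", a1, a3n)[..., None] * a3n
    a1n = a1p / np.linalg.norm(a1p, axis=-1, keepdims=True)
    return a1n, a3n


__all__ = [
    "POS_BASE",
    "NM_PER_UNIT",
    "ValidationError",
    "Nucleotide",
    "Topology",
    "Configuration",
    "Trajectory",
    "InMemoryTrajectory",
    "base_site_position",
    "base_site_positions",
    "orthonormalize_pair",
]
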