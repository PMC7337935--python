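"""Readers and writers for the oxDNA plain-text file family.

Covers topology, configuration/trajectory, designed-pair lists, mutual-trap
external-force files, space-separated index files, sequence CSV export and
the three viewer overlay JSON formats (scalar per particle, vector per
particle, free arrow pairs).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core import (
    Configuration,
    InMemoryTrajectory,
    Nucleotide,
    Topology,
    Trajectory,
    ValidationError,
)


class ParseError(ValueError):
    """Raised on malformed input files; message carries location info."""


# ---------------------------------------------------------------------------
# designed pairs / forces
# ---------------------------------------------------------------------------

class DesignedPairs:
    """Unordered, non-overlapping (i, j) base-pair set intended by a design."""

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        canon = set()
        seen: dict[int, tuple[int, int]] = {}
        for i, j in pairs:
            if i == j:
                raise ValidationError(f"pair ({i}, {j}) pairs a base with itself")
            p = (min(i, j), max(i, j))
            if p in canon:
                continue
            for k in p:
                if k in seen:
                    raise ValidationError(
                        f"nucleotide {k} appears in two pairs: {seen[k]} and {p}"
                    )
                seen[k] = p
            canon.add(p)
        self.pairs: frozenset[tuple[int, int]] = frozenset(canon)
        self._partner = {i: (j if i == a else a) for a, j in canon for i in (a, j)}

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __eq__(self, other) -> bool:
        return isinstance(other, DesignedPairs) and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(self.pairs)

    def partner(self, i: int) -> Optional[int]:
        return self._partner.get(i)

    def validate_against(self, topology: Topology) -> None:
        n = topology.n_nucleotides
        for i, j in self.pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"pair ({i}, {j}) outside topology of {n}")


@dataclass(frozen=True)
class MutualTrap:
    particle: int
    ref_particle: int
    stiffness: float
    r0: float

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValidationError("trap stiffness must be positive")
        if self.particle == self.ref_particle:
            raise ValidationError("trap cannot reference its own particle")


@dataclass
class MutualTrapSet:
    traps: list[MutualTrap] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traps)


def read_pairs(path: Union[str, os.PathLike]) -> DesignedPairs:
    """One whitespace-delimited ``i j`` pair per line; blank lines ignored."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 2:
                raise ParseError(f"{path}:{lineno}: expected two ids, got {line!r}")
            pairs.append((int(toks[0]), int(toks[1])))
    return DesignedPairs(pairs)


def write_pairs(pairs: DesignedPairs, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for i, j in pairs:
            fh.write(f"{i} {j}\n")


def pairs_to_forces(
    pairs: DesignedPairs, stiffness: float = 0.09, r0: float = 1.2
) -> MutualTrapSet:
    """Two reciprocal mutual traps per designed pair."""
    traps = []
    for i, j in pairs:
        traps.append(MutualTrap(i, j, stiffness, r0))
        traps.append(MutualTrap(j, i, stiffness, r0))
    return MutualTrapSet(traps)


def forces_to_pairs(trapset: MutualTrapSet) -> DesignedPairs:
    """Collapse reciprocal trap couples back into unordered pairs."""
    directed = {(t.particle, t.ref_particle) for t in trapset.traps}
    orphans = [ij for ij in directed if (ij[1], ij[0]) not in directed]
    if orphans:
        raise ValidationError(f"unpaired traps (no reciprocal): {sorted(orphans)}")
    return DesignedPairs({(min(i, j), max(i, j)) for i, j in directed})


def write_forces(trapset: MutualTrapSet, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for t in trapset.traps:
            fh.write(
                "{\n"
                "type = mutual_trap\n"
                f"particle = {t.particle}\n"
                f"ref_particle = {t.ref_particle}\n"
                f"stiff = {t.stiffness:g}\n"
                f"r0 = {t.r0:g}\n"
                "PBC = 1\n"
                "}\n"
            )


def read_forces(path: Union[str, os.PathLike]) -> MutualTrapSet:
    traps: list[MutualTrap] = []
    block: dict[str, str] = {}
    in_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("{"):
                in_block, block = True, {}
            elif line.startswith("}"):
                if not in_block:
                    raise ParseError(f"{path}:{lineno}: unmatched '}}'")
                in_block = False
                if block.get("type") != "mutual_trap":
                    continue
                try:
                    traps.append(
                        MutualTrap(
                            particle=int(block["particle"]),
                            ref_particle=int(block["ref_particle"]),
                            stiffness=float(block["stiff"]),
                            r0=float(block["r0"]),
                        )
                    )
                except KeyError as e:
                    raise ParseError(f"{path}:{lineno}: trap missing field {e}")
            elif "=" in line:
                key, _, val = line.partition("=")
                block[key.strip()] = val.strip()
    if in_block:
        raise ParseError(f"{path}: unterminated trap block")
    return MutualTrapSet(traps)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def read_topology(path: Union[str, os.PathLike]) -> Topology:
    """Classic oxDNA topology dialect: ``N n_strands`` header, then one
    ``strand base n3 n5`` line per nucleotide; -1 encodes no neighbor."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ParseError(f"{path}:1: malformed header {header!r}")
        n, n_strands = int(header[0]), int(header[1])
        nts = []
        for lineno, line in enumerate(fh, 2):
            toks = line.split()
            if not toks:
                continue
            if len(toks) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {line!r}")
            strand, base, n3, n5 = int(toks[0]), toks[1], int(toks[2]), int(toks[3])
            nts.append(
                Nucleotide(
                    global_id=len(nts),
                    strand_id=strand,
                    base=base,
                    neighbor_3=None if n3 == -1 else n3,
                    neighbor_5=None if n5 == -1 else n5,
                )
            )
    if len(nts) != n:
        raise ParseError(
            f"{path}: header declares {n} nucleotides but body has {len(nts)} lines"
        )
    topo = Topology(nts)
    if topo.n_strands != n_strands:
        raise ParseError(
            f"{path}: header declares {n_strands} strands but body has {topo.n_strands}"
        )
    return topo


def write_topology(topology: Topology, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{topology.n_nucleotides} {topology.n_strands}\n")
        for nt in topology.nucleotides:
            n3 = -1 if nt.neighbor_3 is None else nt.neighbor_3
            n5 = -1 if nt.neighbor_5 is None else nt.neighbor_5
            fh.write(f"{nt.strand_id} {nt.base} {n3} {n5}\n")


# ---------------------------------------------------------------------------
# configurations / trajectories
# ---------------------------------------------------------------------------

_VERSOR_FIX_TOL = 1e-3


def _parse_frame(lines: list[str], n: int, frame_idx: int) -> Configuration:
    if len(lines) < 3 + n:
        raise ParseError(
            f"frame {frame_idx}: expected {n} particle lines, got {len(lines) - 3}"
        )
    t = float(lines[0].partition("=")[2])
    box = np.array([float(x) for x in lines[1].partition("=")[2].split()])
    energies = np.array([float(x) for x in lines[2].partition("=")[2].split()])
    body = lines[3:]
    if len(body) != n:
        raise ParseError(
            f"frame {frame_idx}: expected {n} particle lines, got {len(body)}"
        )
    data = np.empty((n, 9))
    for i, line in enumerate(body):
        toks = line.split()
        if len(toks) < 9:
            raise ParseError(
                f"frame {frame_idx}: particle line {i} has {len(toks)} columns, need >= 9"
            )
        data[i] = [float(x) for x in toks[:9]]
    pos, a1, a3 = data[:, 0:3], data[:, 3:6], data[:, 6:9]
    for name, arr in (("a1", a1), ("a3", a3)):
        norms = np.linalg.norm(arr, axis=1)
        off = np.abs(norms - 1.0)
        if off.max(initial=0.0) > _VERSOR_FIX_TOL:
            raise ValidationError(
                f"frame {frame_idx}: non-unit {name} versor "
                f"(|norm-1| = {off.max():.2e} > {_VERSOR_FIX_TOL})"
            )
        # renormalize only meaningfully off-unit rows, so that emitting at
        # fixed precision and re-reading is value-identical
        fix = off > 1e-6
        if fix.any():
            arr[fix] /= norms[fix, None]
    return Configuration(time=t, box=box, energies=energies, positions=pos, a1=a1, a3=a3)


class FileTrajectory(Trajectory):
    """Lazily indexed text trajectory; frames fetched by byte offset.

    Picklable (holds only path + offsets + topology), so it can be shipped
    to worker processes for chunked analysis.
    """

    def __init__(self, path: Union[str, os.PathLike], topology: Topology):
        self.path = os.fspath(path)
        self.topology = topology
        self._offsets: list[int] = []
        self._index()

    def _index(self) -> None:
        with open(self.path, "rb") as fh:
            offset = 0
            for line in fh:
                if line.lstrip().startswith(b"t"):
                    stripped = line.lstrip()
                    if stripped.startswith(b"t =") or stripped.startswith(b"t="):
                        self._offsets.append(offset)
                offset += len(line)
        if not self._offsets:
            raise ParseError(f"{self.path}: no frames found (no 't = ...' headers)")

    def __len__(self) -> int:
        return len(self._offsets)

    def __getitem__(self, k: int) -> Configuration:
        if not 0 <= k < len(self._offsets):
            raise IndexError(f"frame {k} out of range [0, {len(self._offsets)})")
        n = self.topology.n_nucleotides
        lines: list[str] = []
        with open(self.path) as fh:
            fh.seek(self._offsets[k])
            for line in fh:
                if lines and (line.startswith("t =") or line.startswith("t=")):
                    break
                if line.strip():
                    lines.append(line)
                if len(lines) >= n + 3:
                    break
        return _parse_frame(lines, n, k)

    def __getstate__(self):
        return {"path": self.path, "topology": self.topology, "_offsets": self._offsets}

    def __setstate__(self, state):
        self.__dict__.update(state)


def read_configuration(path: Union[str, os.PathLike], topology: Topology) -> Configuration:
    with open(path) as fh:
        lines = [line for line in fh if line.strip()]
    return _parse_frame(lines, topology.n_nucleotides, 0)


def read_trajectory(path: Union[str, os.PathLike], topology: Topology) -> FileTrajectory:
    """Index a trajectory file; validates every frame's particle count lazily."""
    traj = FileTrajectory(path, topology)
    # eager structural validation of first and last frames; full validation
    # happens as frames are accessed
    traj[0]
    traj[len(traj) - 1]
    return traj


def write_configuration(config: Configuration, fh, precision: int = 8) -> None:
    p = precision
    fh.write(f"t = {config.time:g}\n")
    fh.write("b = " + " ".join(f"{x:.{p}f}" for x in config.box) + "\n")
    fh.write("E = " + " ".join(f"{x:.{p}f}" for x in config.energies) + "\n")
    zeros = " ".join(["0"] * 6)
    for i in range(config.n):
        row = np.concatenate([config.positions[i], config.a1[i], config.a3[i]])
        fh.write(" ".join(f"{x:.{p}f}" for x in row) + f" {zeros}\n")


def write_trajectory(
    traj_or_frames: Union[Trajectory, Sequence[Configuration]],
    path: Union[str, os.PathLike],
    precision: int = 8,
) -> None:
    frames = (
        iter(traj_or_frames)
        if isinstance(traj_or_frames, Trajectory)
        else iter(traj_or_frames)
    )
    with open(path, "w") as fh:
        for config in frames:
            write_configuration(config, fh, precision=precision)


# ---------------------------------------------------------------------------
# index files
# ---------------------------------------------------------------------------

def read_index_file(path: Union[str, os.PathLike]) -> list[int]:
    """Whitespace-separated global ids, order preserved; duplicates rejected."""
    with open(path) as fh:
        toks = fh.read().split()
    ids = [int(t) for t in toks]
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate id {i} in index file {path}")
        seen.add(i)
    return ids


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

@dataclass
class ColorOverlay:
    """One scalar per nucleotide, rendered as a colormap in the viewer."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class VectorOverlay:
    """One 3-vector per nucleotide, rendered as per-particle arrows."""

    name: str
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)


@dataclass
class ArrowOverlay:
    """Free arrows: (origin, direction) 3-vector pairs, any count."""

    arrows: list[tuple[np.ndarray, np.ndarray]]
    name: str = "arrows"


Overlay = Union[ColorOverlay, VectorOverlay, ArrowOverlay]


def _round6(values: Iterable[float]) -> list[float]:
    # <= 6 significant digits keeps overlay files small; precision is visual
    return [float(f"{v:.6g}") for v in values]


def write_overlay(overlay: Overlay, path: Union[str, os.PathLike]) -> None:
    if isinstance(overlay, ColorOverlay):
        payload = {overlay.name: _round6(overlay.values)}
    elif isinstance(overlay, VectorOverlay):
        payload = {overlay.name: _round6(overlay.vectors.ravel())}
    elif isinstance(overlay, ArrowOverlay):
        flat: list[float] = []
        for origin, direction in overlay.arrows:
            flat.extend(np.asarray(origin, dtype=float).ravel())
            flat.extend(np.asarray(direction, dtype=float).ravel())
        if not all(np.isfinite(flat)):
            raise ValidationError("arrow overlay contains non-finite components")
        payload = {overlay.name: _round6(flat)}
    else:  # pragma: no cover
        raise TypeError(f"unknown overlay type {type(overlay)!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_overlay(path: Union[str, os.PathLike]) -> dict[str, list[float]]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or not all(
        isinstance(v, list) for v in data.values()
    ):
        raise ParseError(f"{path}: not an overlay JSON object")
    return data


# ---------------------------------------------------------------------------
# sequence export
# ---------------------------------------------------------------------------

def export_sequences_csv(topology: Topology, path: Union[str, os.PathLike]) -> None:
    """One row per strand: id, length, 5'->3' sequence, circular flag."""
    with open(path, "w") as fh:
        fh.write("strand,length,sequence,circular\n")
        for sid in topology.strand_ids:
            seq = topology.strand_sequence_5to3(sid)
            circ = "true" if topology.is_circular(sid) else "false"
            fh.write(f"{sid},{len(seq)},{seq},{circ}\n")


__all__ = [
    "ParseError",
    "DesignedPairs",
    "MutualTrap",
    "MutualTrapSet",
    "read_pairs",
    "write_pairs",
    "pairs_to_forces",
    "forces_to_pairs",
    "read_forces",
    "write_forces",
    "read_topology",
    "write_topology",
    "read_configuration",
    "read_trajectory",
    "write_configuration",
    "write_trajectory",
    "FileTrajectory",
    "read_index_file",
    "ColorOverlay",
    "VectorOverlay",
    "ArrowOverlay",
    "write_overlay",
    "read_overlay",
    "export_sequences_csv",
]
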