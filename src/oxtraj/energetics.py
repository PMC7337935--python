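"""Hydrogen-bond detection, designed-pair occupancy and energy overlays.

The full coarse-grained force field is not evaluated here.  Bonds are
detected either geometrically (base sites close, bases complementary, a1
versors antiparallel) or from an externally produced per-interaction energy
table, where a base-pairing energy below -0.1 (simulation energy units,
~k_BT scale) marks a formed hydrogen bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .core import Configuration, Trajectory, base_site_positions
from .io_oxdna import ColorOverlay, DesignedPairs

#: default hydrogen-bond energy threshold (simulation energy units)
HB_ENERGY_THRESHOLD = -0.1

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class BondCriterion:
    mode: str = "geometric"  # "geometric" | "energy"
    energy_threshold: float = HB_ENERGY_THRESHOLD
    site_cutoff: float = 0.85
    antiparallel_cutoff: float = -0.7
    allow_wobble: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("geometric", "energy"):
            raise ValueError(f"unknown bond criterion mode {self.mode!r}")
        if self.mode == "energy" and self.energy_threshold >= 0:
            raise ValueError("energy threshold must be negative")

    def complementary(self, b1: str, b2: str) -> bool:
        key = (b1.upper(), b2.upper())
        return key in _WC or (self.allow_wobble and key in _WOBBLE)


@dataclass
class InteractionRow:
    frame: int
    i: int
    j: int
    kind: str
    energy: float


@dataclass
class InteractionTable:
    """Externally computed per-interaction energies (TSV-backed)."""

    rows: list[InteractionRow] = field(default_factory=list)

    def frame_slice(self, frame: int) -> list[InteractionRow]:
        return [r for r in self.rows if r.frame == frame]

    @classmethod
    def read_tsv(cls, path) -> "InteractionTable":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                toks = line.split()
                if not toks or toks[0].startswith("#") or toks[0] == "frame":
                    continue
                if len(toks) != 5:
                    raise ValueError(
                        f"{path}:{lineno}: expected 5 columns "
                        "(frame i j kind energy)"
                    )
                rows.append(
                    InteractionRow(
                        frame=int(toks[0]),
                        i=int(toks[1]),
                        j=int(toks[2]),
                        kind=toks[3],
                        energy=float(toks[4]),
                    )
                )
        table = cls(rows)
        table.validate()
        return table

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\ti\tj\tkind\tenergy\n")
            for r in self.rows:
                fh.write(f"{r.frame}\t{r.i}\t{r.j}\t{r.kind}\t{r.energy:.8g}\n")

    def validate(self) -> None:
        for r in self.rows:
            if not np.isfinite(r.energy):
                raise ValueError(f"non-finite energy in row {r}")
            if r.i < 0 or r.j < 0:
                raise ValueError(f"negative id in row {r}")


@dataclass
class OccupancyResult:
    per_nucleotide: np.ndarray
    per_pair: dict[tuple[int, int], float]


def detect_bonds(
    config: Configuration,
    criterion: BondCriterion,
    bases: Optional[list[str]] = None,
    energies: Optional[Iterable[InteractionRow]] = None,
) -> set[tuple[int, int]]:
    """Hydrogen-bonded pairs of one configuration; output is an involution
    (at most one bond per base; best energy / closest site wins)."""
    if criterion.mode == "energy":
        if energies is None:
            raise ValueError("energy mode requires an interaction-table slice")
        candidates = [
            (r.energy, tuple(sorted((r.i, r.j))))
            for r in energies
            if r.kind.upper() in ("HB", "HYDROGEN_BOND")
            and r.energy < criterion.energy_threshold
        ]
        candidates.sort(key=lambda t: (t[0], t[1]))
    else:
        if bases is None:
            raise ValueError("geometric mode requires per-nucleotide base symbols")
        sites = base_site_positions(config)
        tree = cKDTree(sites)
        raw = tree.query_pairs(criterion.site_cutoff)
        candidates = []
        for i, j in raw:
            if not criterion.complementary(bases[i], bases[j]):
                continue
            if np.dot(config.a1[i], config.a1[j]) >= criterion.antiparallel_cutoff:
                continue
            dist = float(np.linalg.norm(sites[i] - sites[j]))
            candidates.append((dist, tuple(sorted((i, j)))))
        candidates.sort(key=lambda t: (t[0], t[1]))
    bonded: set[tuple[int, int]] = set()
    used: set[int] = set()
    for _, (i, j) in candidates:
        if i in used or j in used:
            continue
        bonded.add((i, j))
        used.update((i, j))
    return bonded


def bond_occupancy(
    traj: Trajectory,
    designed: DesignedPairs,
    criterion: Optional[BondCriterion] = None,
    table: Optional[InteractionTable] = None,
) -> tuple[OccupancyResult, ColorOverlay]:
    """Fraction of frames in which each designed pair is detected as bonded.

    Nucleotides without a designed complement get occupancy exactly 0.
    """
    criterion = criterion or BondCriterion()
    designed.validate_against(traj.topology)
    bases = [nt.base for nt in traj.topology.nucleotides]
    counts = {p: 0 for p in designed.pairs}
    n_frames = len(traj)
    for k in range(n_frames):
        config = traj[k]
        rows = table.frame_slice(k) if table is not None else None
        bonds = detect_bonds(config, criterion, bases=bases, energies=rows)
        for p in counts:
            if p in bonds:
                counts[p] += 1
    per_pair = {p: counts[p] / n_frames for p in counts}
    per_nt = np.zeros(traj.topology.n_nucleotides)
    for (i, j), frac in per_pair.items():
        per_nt[i] = frac
        per_nt[j] = frac
    return (
        OccupancyResult(per_nucleotide=per_nt, per_pair=per_pair),
        ColorOverlay(name="bond occupancy", values=per_nt),
    )


def mean_energy_overlay(
    table: InteractionTable, n: int, frame_count: int
) -> ColorOverlay:
    """Per nucleotide: half of each interaction energy it joins, averaged
    over frames.  Totals are conserved: sum(values) * frame_count equals the
    table's total energy."""
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    acc = np.zeros(n)
    for r in table.rows:
        if r.i >= n or r.j >= n:
            raise ValueError(f"row references id beyond N={n}: {r}")
        acc[r.i] += 0.5 * r.energy
        acc[r.j] += 0.5 * r.energy
    return ColorOverlay(name="mean energy", values=acc / frame_count)


def current_pairs_to_designed(
    config: Configuration,
    topology,
    criterion: Optional[BondCriterion] = None,
    table_rows: Optional[Iterable[InteractionRow]] = None,
) -> DesignedPairs:
    """Snapshot the bonds of a single configuration as a designed-pairs set."""
    criterion = criterion or BondCriterion()
    bases = [nt.base for nt in topology.nucleotides]
    bonds = detect_bonds(config, criterion, bases=bases, energies=table_rows)
    return DesignedPairs(bonds)


__all__ = [
    "HB_ENERGY_THRESHOLD",
    "BondCriterion",
    "InteractionRow",
    "InteractionTable",
    "OccupancyResult",
    "detect_bonds",
    "bond_occupancy",
    "mean_energy_overlay",
    "current_pairs_to_designed",
]
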