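"""DBSCAN over per-frame order parameters; per-cluster trajectory export.

Order parameters can be anything with one row per frame: principal-component
projections, inter-nucleotide distances, or user-supplied columns.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.cluster import DBSCAN as _SkDBSCAN

from .core import Configuration, Trajectory
from .io_oxdna import write_trajectory
from .pca_modes import ProjectionMatrix


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # one int per frame, -1 = noise
    n_clusters: int
    core_flags: np.ndarray

    def members(self, label: int) -> np.ndarray:
        return np.where(self.labels == label)[0]


def _relabel_first_seen(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by first-appearing frame; noise stays -1."""
    out = np.full_like(labels, -1)
    mapping: dict[int, int] = {}
    nxt = 0
    for k, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[k] = mapping[lab]
    return out


def dbscan(
    points: np.ndarray, eps: float, min_samples: int
) -> ClusterAssignment:
    """Standard DBSCAN semantics; clusters numbered by first-seen frame."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] == 0:
        return ClusterAssignment(
            labels=np.empty(0, dtype=int),
            n_clusters=0,
            core_flags=np.empty(0, dtype=bool),
        )
    model = _SkDBSCAN(eps=eps, min_samples=min_samples).fit(points)
    labels = _relabel_first_seen(model.labels_)
    core = np.zeros(points.shape[0], dtype=bool)
    core[model.core_sample_indices_] = True
    return ClusterAssignment(
        labels=labels,
        n_clusters=int(labels.max() + 1) if (labels >= 0).any() else 0,
        core_flags=core,
    )


def estimate_eps(points: np.ndarray, min_samples: int) -> float:
    """Max-curvature (knee) point of the sorted k-distance curve."""
    from sklearn.neighbors import NearestNeighbors

    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    k = min(min_samples, points.shape[0] - 1)
    if k < 1:
        raise ValueError("too few points to estimate eps")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dists, _ = nn.kneighbors(points)
    curve = np.sort(dists[:, -1])
    if curve[-1] == 0:
        return 1e-12
    # discrete second difference; knee = maximum curvature
    if len(curve) < 3:
        return float(curve[-1])
    d2 = np.diff(curve, 2)
    knee = int(np.argmax(d2)) + 1
    return float(max(curve[knee], 1e-12))


def cluster_trajectory(
    traj: Trajectory,
    order_params: Union[ProjectionMatrix, np.ndarray],
    eps: Optional[float] = None,
    min_samples: int = 5,
    output_dir: Optional[Union[str, os.PathLike]] = None,
    save_noise: bool = False,
    precision: int = 8,
) -> tuple[ClusterAssignment, list[str]]:
    """Cluster frames and optionally write one trajectory file per cluster.

    Returns the assignment and the list of files written
    (``cluster_<n>.dat``, plus ``cluster_noise.dat`` if requested).
    """
    coords = (
        order_params.coords
        if isinstance(order_params, ProjectionMatrix)
        else np.asarray(order_params, dtype=float)
    )
    if coords.shape[0] != len(traj):
        raise ValueError(
            f"order parameters have {coords.shape[0]} rows, trajectory has {len(traj)}"
        )
    if eps is None:
        eps = estimate_eps(coords, min_samples)
    assignment = dbscan(coords, eps, min_samples)
    written: list[str] = []
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        if assignment.n_clusters == 0:
            warnings.warn("all frames classified as noise; no cluster files written")
        for lab in range(assignment.n_clusters):
            frames = [traj[int(k)] for k in assignment.members(lab)]
            path = os.path.join(os.fspath(output_dir), f"cluster_{lab}.dat")
            write_trajectory(frames, path, precision=precision)
            written.append(path)
        if save_noise and (assignment.labels == -1).any():
            frames = [traj[int(k)] for k in assignment.members(-1)]
            path = os.path.join(os.fspath(output_dir), "cluster_noise.dat")
            write_trajectory(frames, path, precision=precision)
            written.append(path)
        labels_path = os.path.join(os.fspath(output_dir), "cluster_labels.csv")
        with open(labels_path, "w") as fh:
            fh.write("frame,label\n")
            for k, lab in enumerate(assignment.labels):
                fh.write(f"{k},{lab}\n")
    return assignment, written


def cluster_centroids(
    traj: Trajectory,
    assignment: ClusterAssignment,
    order_params: Union[ProjectionMatrix, np.ndarray],
) -> dict[int, tuple[int, Configuration]]:
    """Per cluster: the member frame minimizing mean distance (in order-
    parameter space) to the other members; ties go to the lowest index."""
    coords = (
        order_params.coords
        if isinstance(order_params, ProjectionMatrix)
        else np.asarray(order_params, dtype=float)
    )
    if coords.ndim == 1:
        coords = coords[:, None]
    out: dict[int, tuple[int, Configuration]] = {}
    for lab in range(assignment.n_clusters):
        members = assignment.members(lab)
        sub = coords[members]
        dists = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
        mean_d = dists.mean(axis=1)
        best = int(members[int(np.argmin(mean_d))])
        out[lab] = (best, traj[best])
    return out


__all__ = [
    "ClusterAssignment",
    "dbscan",
    "estimate_eps",
    "cluster_trajectory",
    "cluster_centroids",
]
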