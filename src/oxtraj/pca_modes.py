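"""Principal component analysis of aligned trajectory motion.

Per-frame positional deviations from a mean reference are flattened to
3N-vectors; the eigendecomposition of their covariance gives motion modes
sorted by descending variance.  After rigid alignment at most 3N - 6
eigenvalues are materially nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Configuration, Trajectory
from .io_oxdna import VectorOverlay
from .superposition import MeanStructureResult, align_trajectory
from . import parallel as _par

#: above this many coordinates, use SVD of the deviation matrix instead of
#: forming the full covariance (identical nonzero spectrum, less memory)
_FULL_EIG_MAX_COORDS = 3 * 3000


@dataclass
class PCABasis:
    mean: Configuration
    eigenvalues: np.ndarray  # descending, length = number of retained modes
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    explained_variance: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class ProjectionMatrix:
    coords: np.ndarray  # (F, k)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _deviation_moment_chunk(traj, start, stop, mean_flat):
    d = mean_flat.shape[0]
    s = np.zeros(d)
    outer = np.zeros((d, d))
    for k in range(start, stop):
        dev = traj[k].positions.ravel() - mean_flat
        s += dev
        outer += np.outer(dev, dev)
    return s, outer, stop - start


def compute_pca(
    traj: Trajectory,
    mean: MeanStructureResult,
    align: bool = True,
    n_cpus: int = 1,
) -> PCABasis:
    """Eigendecomposition of the positional deviation covariance.

    Deviations use positions only (orientation versors are ignored).  The
    covariance uses the 1/F normalization so projection variances match the
    eigenvalues exactly.  Eigenvector signs are fixed so each column's
    largest-magnitude entry is positive.
    """
    if len(traj) < 2:
        raise ValueError("PCA needs at least two frames")
    work = align_trajectory(traj, mean.mean, mean.subset) if align else traj
    mean_flat = mean.mean.positions.ravel()
    d = mean_flat.shape[0]
    f = len(work)
    if d <= _FULL_EIG_MAX_COORDS and d <= 3 * f:
        partials = _par.parallel_map(
            work, _deviation_moment_chunk, n_cpus, args=(mean_flat,)
        )
        outer = np.sum([p[1] for p in partials], axis=0)
        count = sum(p[2] for p in partials)
        # deviations are taken about the provided mean, not re-centered
        cov = outer / count
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        dev = np.empty((f, d))
        for k in range(f):
            dev[k] = work[k].positions.ravel() - mean_flat
        u, sing, vt = np.linalg.svd(dev, full_matrices=False)
        vals = sing**2 / f
        vecs = vt.T
    vals = np.where(np.abs(vals) < 1e-18, 0.0, vals)
    # deterministic sign convention
    for c in range(vecs.shape[1]):
        peak = np.argmax(np.abs(vecs[:, c]))
        if vecs[peak, c] < 0:
            vecs[:, c] = -vecs[:, c]
    total = vals.sum()
    explained = vals / total if total > 0 else np.zeros_like(vals)
    return PCABasis(
        mean=mean.mean,
        eigenvalues=vals,
        eigenvectors=vecs,
        explained_variance=explained,
    )


def project(
    traj: Trajectory,
    basis: PCABasis,
    k: Optional[int] = None,
    align: bool = True,
) -> ProjectionMatrix:
    """Coordinates of each frame on the top-k modes."""
    k = basis.n_modes if k is None else k
    work = align_trajectory(traj, basis.mean, None) if align else traj
    mean_flat = basis.mean.positions.ravel()
    dev = np.stack([c.positions.ravel() - mean_flat for c in work])
    return ProjectionMatrix(coords=dev @ basis.eigenvectors[:, :k])


def reconstruct(basis: PCABasis, coords: np.ndarray) -> np.ndarray:
    """Positions (N, 3) rebuilt from mode coordinates."""
    flat = basis.mean.positions.ravel() + basis.eigenvectors @ np.asarray(coords)
    return flat.reshape(-1, 3)


def mode_overlay(
    basis: PCABasis, n_components: int, weight: str = "eigenvalue"
) -> VectorOverlay:
    """Per-nucleotide arrows: sum of the top modes weighted by eigenvalue
    (or its square root with ``weight='sqrt'``)."""
    if n_components < 0 or n_components > basis.n_modes:
        raise ValueError(f"n_components must be in [0, {basis.n_modes}]")
    d = basis.eigenvectors.shape[0]
    acc = np.zeros(d)
    for m in range(n_components):
        w = basis.eigenvalues[m]
        if weight == "sqrt":
            w = np.sqrt(max(w, 0.0))
        acc += w * basis.eigenvectors[:, m]
    return VectorOverlay(name="pca modes", vectors=acc.reshape(-1, 3))


def scree(basis: PCABasis) -> dict[str, np.ndarray]:
    """Explained-variance table: fractions and their cumulative sum."""
    frac = basis.explained_variance
    return {
        "eigenvalue": basis.eigenvalues.copy(),
        "fraction": frac.copy(),
        "cumulative": np.cumsum(frac),
    }


__all__ = [
    "PCABasis",
    "ProjectionMatrix",
    "compute_pca",
    "project",
    "reconstruct",
    "mode_overlay",
    "scree",
]
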