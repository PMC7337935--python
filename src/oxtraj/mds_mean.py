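"""Mean structure from mean local contact distances via multidimensional
scaling, plus a per-nucleotide local deviation (flexibility) measure.

Only pairs whose trajectory-mean centre-of-mass distance is below a cutoff
(default 2.07 nm, roughly the interhelix gap in an origami) enter the
embedding; missing pairs carry zero weight in the stress
``f = sum_ij (<delta_ij> - d_ij)^2``, which is minimized by SMACOF stress
majorization started from a classical-MDS solution of the geodesic
completion of the contact graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .core import NM_PER_UNIT, Trajectory
from .io_oxdna import ColorOverlay
from . import parallel as _par

#: default contact cutoff, simulation length units (2.07 nm)
R_CUT_DEFAULT = 2.07 / NM_PER_UNIT


class DisconnectedMapError(ValueError):
    pass


class CollapseWarning(UserWarning):
    """The embedding collapsed toward a single point (known failure mode)."""


@dataclass
class ContactMap:
    """Sparse symmetric map of trajectory-mean pair distances <= r_cut."""

    n: int
    i_idx: np.ndarray
    j_idx: np.ndarray
    mean_dist: np.ndarray
    r_cut: float

    def __post_init__(self) -> None:
        self.i_idx = np.asarray(self.i_idx, dtype=int)
        self.j_idx = np.asarray(self.j_idx, dtype=int)
        self.mean_dist = np.asarray(self.mean_dist, dtype=float)
        if (self.i_idx >= self.j_idx).any():
            raise ValueError("contact map entries must be stored with i < j")

    @property
    def n_pairs(self) -> int:
        return len(self.mean_dist)

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.i_idx.tolist(), self.j_idx.tolist()))

    def partners(self, i: int) -> list[int]:
        out = self.j_idx[self.i_idx == i].tolist()
        out += self.i_idx[self.j_idx == i].tolist()
        return sorted(out)


@dataclass
class EmbeddedStructure:
    """Centre-of-mass coordinates only (orientation is lost), centered."""

    coordinates: np.ndarray
    stress: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.isfinite(self.coordinates).all():
            raise ValueError("embedded coordinates must be finite")


def _distance_sum_chunk(traj, start, stop):
    n = traj.topology.n_nucleotides
    acc = np.zeros((n, n))
    for k in range(start, stop):
        p = traj[k].positions
        diff = p[:, None, :] - p[None, :, :]
        acc += np.sqrt(np.sum(diff * diff, axis=2))
    return acc, stop - start


def mean_distance_map(
    traj: Trajectory, r_cut: float = R_CUT_DEFAULT, n_cpus: int = 1
) -> ContactMap:
    """Trajectory mean of all pairwise COM distances, thresholded at r_cut."""
    if len(traj) < 1:
        raise ValueError("need at least one frame")
    partials = _par.parallel_map(traj, _distance_sum_chunk, n_cpus)
    total = np.sum([p[0] for p in partials], axis=0)
    count = sum(p[1] for p in partials)
    mean = total / count
    n = mean.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = mean[iu, ju] <= r_cut
    return ContactMap(
        n=n, i_idx=iu[keep], j_idx=ju[keep], mean_dist=mean[iu, ju][keep], r_cut=r_cut
    )


def _classical_mds(dist: np.ndarray, dim: int = 3) -> np.ndarray:
    d2 = dist**2
    n = dist.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def mds_embed(
    cmap: ContactMap,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: Optional[np.ndarray] = None,
    refine: bool = True,
) -> EmbeddedStructure:
    """Embed the contact map in 3D by weighted SMACOF stress majorization.

    Majorization alone converges slowly in the soft long-wavelength bending
    modes of banded contact graphs, so by default the result is polished
    with an L-BFGS minimization of the same stress (``refine=False`` gives
    pure SMACOF).

    Raises :class:`DisconnectedMapError` when the contact graph has more than
    one component (each fragment could float freely).  Emits a
    :class:`CollapseWarning` when the solution degenerates to a point.
    """
    n = cmap.n
    w = csr_matrix(
        (np.ones(cmap.n_pairs), (cmap.i_idx, cmap.j_idx)), shape=(n, n)
    )
    w = w + w.T
    n_comp, labels = connected_components(w, directed=False)
    if n_comp > 1:
        frags = [np.where(labels == c)[0].tolist() for c in range(n_comp)]
        raise DisconnectedMapError(
            f"contact graph has {n_comp} components: "
            + "; ".join(str(f[:8]) + ("..." if len(f) > 8 else "") for f in frags)
        )

    delta = csr_matrix(
        (cmap.mean_dist, (cmap.i_idx, cmap.j_idx)), shape=(n, n)
    )
    delta = delta + delta.T

    if init is not None:
        x = np.array(init, dtype=float)
    else:
        geo = shortest_path(delta, method="D", directed=False)
        x = _classical_mds(geo)
        # tiny deterministic jitter breaks exact-symmetry stationary points
        rng = np.random.default_rng(seed)
        x = x + 1e-9 * rng.standard_normal(x.shape)

    wd = np.asarray(w.todense())
    dd = np.asarray(delta.todense())
    # Guttman transform with the pseudo-inverse of the weight Laplacian
    v = np.diag(wd.sum(axis=1)) - wd
    v_pinv = np.linalg.pinv(v)

    def stress_of(xx: np.ndarray) -> float:
        d = np.linalg.norm(xx[cmap.i_idx] - xx[cmap.j_idx], axis=1)
        return float(np.sum((cmap.mean_dist - d) ** 2))

    prev = stress_of(x)
    scale2 = float(np.mean(cmap.mean_dist**2)) if cmap.n_pairs else 1.0
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dd / np.where(d > 0, d, 1.0), 0.0)
        b = -wd * ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = v_pinv @ (b @ x)
        cur = stress_of(x)
        if prev > 0 and (prev - cur) / max(prev, 1e-300) < tol:
            prev = cur
            break
        if cur < 1e-14 * scale2 * cmap.n_pairs:
            prev = cur
            break
        prev = cur

    if refine and cmap.n_pairs:
        x, prev = _lbfgs_refine(x, cmap)

    x = x - x.mean(axis=0)
    if n > 3:
        bbox = x.max(axis=0) - x.min(axis=0)
        expected = float(np.max(cmap.mean_dist)) if cmap.n_pairs else 1.0
        if np.linalg.norm(bbox) < 1e-4 * expected:
            warnings.warn(
                "MDS embedding collapsed to a point; the mean contact map "
                "does not determine a 3D structure at this size",
                CollapseWarning,
            )
    return EmbeddedStructure(coordinates=x, stress=prev)


def _lbfgs_refine(x: np.ndarray, cmap: ContactMap) -> tuple[np.ndarray, float]:
    from scipy.optimize import minimize

    n = cmap.n
    i_idx, j_idx, delta = cmap.i_idx, cmap.j_idx, cmap.mean_dist

    def fg(flat):
        xx = flat.reshape(n, 3)
        dv = xx[i_idx] - xx[j_idx]
        d = np.linalg.norm(dv, axis=1)
        r = delta - d
        coef = (-2.0 * r / np.maximum(d, 1e-12))[:, None] * dv
        g = np.zeros((n, 3))
        np.add.at(g, i_idx, coef)
        np.add.at(g, j_idx, -coef)
        return float(np.sum(r * r)), g.ravel()

    res = minimize(
        fg,
        x.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-14},
    )
    return res.x.reshape(n, 3), float(res.fun)


def _deviation_chunk(traj, start, stop, i_idx, j_idx):
    s = np.zeros(len(i_idx))
    s2 = np.zeros(len(i_idx))
    for k in range(start, stop):
        p = traj[k].positions
        d = np.linalg.norm(p[i_idx] - p[j_idx], axis=1)
        s += d
        s2 += d * d
    return s, s2, stop - start


def local_deviation(
    traj: Trajectory,
    cmap: ContactMap,
    mode: str = "std",
    units: str = "nm",
    n_cpus: int = 1,
) -> ColorOverlay:
    """Per-nucleotide mean (over retained partners) of the per-pair distance
    spread across frames.  ``mode`` selects std (default) or mean absolute
    deviation from the pair mean."""
    if mode not in ("std", "mad"):
        raise ValueError("mode must be 'std' or 'mad'")
    partials = _par.parallel_map(
        traj, _deviation_chunk, n_cpus, args=(cmap.i_idx, cmap.j_idx)
    )
    s = np.sum([p[0] for p in partials], axis=0)
    s2 = np.sum([p[1] for p in partials], axis=0)
    count = sum(p[2] for p in partials)
    mean = s / count
    var = np.clip(s2 / count - mean**2, 0.0, None)
    if mode == "std":
        spread = np.sqrt(var)
    else:
        # second pass for exact MAD about the per-pair mean
        acc = np.zeros(len(cmap.i_idx))
        for c in traj:
            d = np.linalg.norm(
                c.positions[cmap.i_idx] - c.positions[cmap.j_idx], axis=1
            )
            acc += np.abs(d - mean)
        spread = acc / count
    per_nt = np.zeros(cmap.n)
    n_partners = np.zeros(cmap.n)
    np.add.at(per_nt, cmap.i_idx, spread)
    np.add.at(per_nt, cmap.j_idx, spread)
    np.add.at(n_partners, cmap.i_idx, 1)
    np.add.at(n_partners, cmap.j_idx, 1)
    with np.errstate(invalid="ignore"):
        per_nt = np.where(n_partners > 0, per_nt / np.maximum(n_partners, 1), 0.0)
    if units == "nm":
        per_nt = per_nt * NM_PER_UNIT
    elif units != "sim":
        raise ValueError("units must be 'nm' or 'sim'")
    return ColorOverlay(name=f"local contact deviation ({units})", values=per_nt)


__all__ = [
    "R_CUT_DEFAULT",
    "ContactMap",
    "EmbeddedStructure",
    "DisconnectedMapError",
    "CollapseWarning",
    "mean_distance_map",
    "mds_embed",
    "local_deviation",
]
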