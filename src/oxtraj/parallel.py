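"""Chunked trajectory parallelization.

A trajectory is split into as many contiguous chunks as there are workers;
each worker runs a pure per-chunk function and partial results are combined
in chunk order, so output is independent of scheduling.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .core import Trajectory


@dataclass(frozen=True)
class ChunkPlan:
    """Disjoint, ordered half-open frame ranges covering [0, frame_count)."""

    ranges: tuple[tuple[int, int], ...]

    @property
    def n_chunks(self) -> int:
        return len(self.ranges)


def plan_chunks(frame_count: int, n_cpus: int) -> ChunkPlan:
    """Split frames as evenly as possible; chunk sizes differ by at most 1."""
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    if n_cpus < 1:
        raise ValueError("n_cpus must be >= 1")
    n = min(n_cpus, frame_count)
    base, extra = divmod(frame_count, n)
    ranges = []
    start = 0
    for k in range(n):
        size = base + (1 if k < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ChunkPlan(ranges=tuple(ranges))


def _run_chunk(payload):
    fn, traj, start, stop, args = payload
    return fn(traj, start, stop, *args)


def parallel_map(
    traj: Trajectory,
    chunk_fn: Callable,
    n_cpus: int = 1,
    args: Sequence = (),
    reducer: Optional[Callable] = None,
):
    """Apply ``chunk_fn(traj, start, stop, *args)`` over a chunk plan.

    ``chunk_fn`` must be a picklable top-level function that depends only on
    the frames in its range.  Partials are combined in chunk order; pass a
    ``reducer`` to fold them, otherwise the ordered list is returned.
    """
    plan = plan_chunks(len(traj), n_cpus)
    payloads = [(chunk_fn, traj, s, e, tuple(args)) for s, e in plan.ranges]
    if n_cpus <= 1 or plan.n_chunks == 1:
        partials = [_run_chunk(p) for p in payloads]
    else:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(processes=plan.n_chunks) as pool:
            partials = pool.map(_run_chunk, payloads)
    if reducer is not None:
        return reducer(partials)
    return partials


__all__ = ["ChunkPlan", "plan_chunks", "parallel_map"]
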