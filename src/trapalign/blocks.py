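"""Trapezoidal ("ladder") block parallelism over the DP matrix.

The matrix is partitioned into L x L tiles (edge tiles ragged).  Tiles on one
anti-diagonal wave (constant ``bi + bj``) touch disjoint cell ranges and
depend only on the previous wave, so each wave is dispatched to a worker pool
with a barrier between waves.  Neighbouring tiles exchange *boundary packets*:
the rim state in difference form plus an absolute anchor score at the tile's
outer corner, so that anchored prefix sums reproduce the oracle's absolute
scores along both edges.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigError, InternalError, TrapalignError
from .scoring import NEG_INF, ScoringScheme


@dataclass(frozen=True)
class BoundaryPacket:
    """Rim state a finished tile hands to one neighbour.

    ``diffs`` are the differences along the edge (dH for a horizontal edge,
    dV for a vertical one); ``gap_rel`` the matching gap state relative to
    each rim cell's own score (E - M along a horizontal edge, F - M along a
    vertical one); ``anchor`` the absolute score at the edge's upper-left
    outer corner, so ``anchor + cumsum(diffs)`` is the absolute rim.
    """

    anchor: int
    diffs: np.ndarray
    gap_rel: np.ndarray

    def absolute(self) -> np.ndarray:
        """Absolute scores along the rim (anchor excluded)."""
        return self.anchor + np.cumsum(self.diffs)


@dataclass(frozen=True)
class BlockTask:
    """One L x L (possibly ragged) tile of the DP matrix."""

    bi: int
    bj: int
    row_start: int  # half-open 1-based cell ranges
    row_stop: int
    col_start: int
    col_stop: int

    @property
    def wave(self) -> int:
        return self.bi + self.bj

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_stop - self.row_start, self.col_stop - self.col_start


@dataclass
class WavePlan:
    """Anti-diagonal schedule: waves of mutually independent tiles."""

    n_block_rows: int
    n_block_cols: int
    waves: list[list[BlockTask]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return self.n_block_rows * self.n_block_cols


def partition_matrix(n: int, m: int, L: int) -> WavePlan:
    """Tile an n x m matrix into ceil(n/L) x ceil(m/L) blocks grouped by wave.

    Edge blocks shrink rather than padding the matrix; padding happens only
    inside the stripe layout of a short final segment.  Enumeration order
    within a wave is deterministic (increasing block row).
    """
    if n < 1 or m < 1 or L < 1:
        raise ConfigError("n, m and block side must all be >= 1")
    nbr = -(-n // L)
    nbc = -(-m // L)
    plan = WavePlan(nbr, nbc)
    plan.waves = [[] for _ in range(nbr + nbc - 1)]
    for bi in range(nbr):
        for bj in range(nbc):
            task = BlockTask(
                bi,
                bj,
                row_start=bi * L + 1,
                row_stop=min((bi + 1) * L, n) + 1,
                col_start=bj * L + 1,
                col_stop=min((bj + 1) * L, m) + 1,
            )
            plan.waves[task.wave].append(task)
    return plan


def synthetic_top_packet(col_start: int, width: int, scheme: ScoringScheme) -> BoundaryPacket:
    """Row-0 boundary for a block in the top block row: the gap-cost series."""
    o, e = scheme.gap_open, scheme.gap_extend
    dH = np.full(width, e, dtype=np.int64)
    if col_start == 1:
        dH[0] = o + e
    anchor = 0 if col_start == 1 else o + (col_start - 1) * e
    return BoundaryPacket(anchor, dH, np.full(width, NEG_INF, dtype=np.int64))


def synthetic_left_packet(row_start: int, height: int, scheme: ScoringScheme) -> BoundaryPacket:
    """Column-0 boundary for a block in the left block column."""
    o, e = scheme.gap_open, scheme.gap_extend
    dV = np.full(height, e, dtype=np.int64)
    if row_start == 1:
        dV[0] = o + e
    anchor = 0 if row_start == 1 else o + (row_start - 1) * e
    return BoundaryPacket(anchor, dV, np.full(height, NEG_INF, dtype=np.int64))


def stitch_boundaries(
    left: BoundaryPacket, top: BoundaryPacket, task: BlockTask
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble a block's starting state from its two incoming packets.

    Returns ``(corner_anchor, dH_top, erel_top, dV_left, frel_left)``.  Both
    packets anchor at the block's upper-left outer corner and must agree.
    """
    h, w = task.shape
    if len(top.diffs) != w or len(left.diffs) != h:
        raise InternalError(
            f"packet shapes ({len(top.diffs)}, {len(left.diffs)}) do not match "
            f"block {task.bi},{task.bj} of shape {(h, w)}"
        )
    if left.anchor != top.anchor:
        raise InternalError(
            f"corner anchor mismatch at block {task.bi},{task.bj}: "
            f"left {left.anchor} != top {top.anchor}"
        )
    return int(top.anchor), top.diffs, top.gap_rel, left.diffs, left.gap_rel


class BlockFailure(InternalError):
    """A block computation raised; carries the block coordinates."""

    def __init__(self, task: BlockTask, cause: BaseException):
        super().__init__(f"block ({task.bi},{task.bj}) failed: {cause}")
        self.task = task


def execute_ladder(
    plan: WavePlan,
    worker_count: int,
    block_fn: Callable[[BlockTask, BoundaryPacket, BoundaryPacket], tuple[BoundaryPacket, BoundaryPacket]],
    scheme: ScoringScheme,
) -> BoundaryPacket:
    """Run every wave of the plan, with a barrier between waves.

    ``block_fn(task, top, left) -> (bottom, right)`` computes one tile.  All
    blocks of wave w complete before any block of wave w+1 starts; with
    ``worker_count == 1`` the scheduler degenerates to a plain loop (the
    canonical reference execution).  Results are independent of worker
    scheduling order by construction: each tile's output depends only on its
    input packets.

    Returns the bottom packet of the bottom-right tile; its last absolute rim
    value is the global alignment score.
    """
    if worker_count < 1:
        raise ConfigError("worker count must be >= 1")
    bottoms: dict[tuple[int, int], BoundaryPacket] = {}
    rights: dict[tuple[int, int], BoundaryPacket] = {}

    def inputs(task: BlockTask) -> tuple[BoundaryPacket, BoundaryPacket]:
        h, w = task.shape
        if task.bi == 0:
            top = synthetic_top_packet(task.col_start, w, scheme)
        else:
            top = bottoms.pop((task.bi - 1, task.bj))
        if task.bj == 0:
            left = synthetic_left_packet(task.row_start, h, scheme)
        else:
            left = rights.pop((task.bi, task.bj - 1))
        return top, left

    def run(task: BlockTask, top: BoundaryPacket, left: BoundaryPacket):
        try:
            return task, block_fn(task, top, left)
        except TrapalignError:
            raise  # library errors already carry cell-level context
        except BaseException as exc:  # noqa: BLE001 - re-raised with coordinates
            raise BlockFailure(task, exc) from exc

    last_key = (plan.n_block_rows - 1, plan.n_block_cols - 1)
    pool = ThreadPoolExecutor(max_workers=worker_count) if worker_count > 1 else None
    try:
        for wave in plan.waves:
            staged = [(task, *inputs(task)) for task in wave]
            if pool is None:
                results = [run(*s) for s in staged]
            else:
                results = list(pool.map(lambda s: run(*s), staged))
            for task, (bottom, right) in results:
                key = (task.bi, task.bj)
                if task.bi + 1 < plan.n_block_rows or key == last_key:
                    bottoms[key] = bottom
                if task.bj + 1 < plan.n_block_cols:
                    rights[key] = right
    finally:
        if pool is not None:
            pool.shutdown(wait=True)
    return bottoms[last_key]
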