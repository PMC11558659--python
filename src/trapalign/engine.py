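"""Pairwise global alignment: striped difference blocks on the ladder scheduler.

:func:`align_pairwise` is the user-facing entry point.  It partitions the DP
matrix into L x L tiles (L = lanes x stripes), computes each tile with the
compiled striped difference kernel, threads the anti-diagonal waves, and
reconstructs the optimal global score (and, in traceback mode, a CIGAR) that
is bit-identical to the plain-DP oracle for every legal parameter choice.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .blocks import (
    BlockTask,
    BoundaryPacket,
    execute_ladder,
    partition_matrix,
    stitch_boundaries,
)
from .cigar import cigar_to_string
from .errors import ConfigError, LaneOverflowError, StateError
from .results import AlignmentResult
from .scoring import ScoringScheme, encode, gap_cost
from .stripes import lane_range


@dataclass(frozen=True)
class EngineParams:
    """Tunable knobs of the striped/blocked engine.

    ``lanes`` (S) is the number of elements a lane-vector processes at once;
    ``stripes`` (D) the stripe count per block row; ``threads`` (T) the worker
    count of the ladder scheduler.  The block side is L = S x D unless
    ``block_side`` overrides it (it must then be a multiple of ``lanes``).
    ``delta_width`` selects exact arithmetic or an int8 lane emulation that
    raises on overflow rather than saturating.
    """

    lanes: int = 8
    stripes: int = 4
    threads: int = 1
    block_side: int | None = None
    traceback: bool = False
    delta_width: str = "exact"

    def __post_init__(self) -> None:
        if self.lanes < 1 or self.stripes < 1 or self.threads < 1:
            raise ConfigError("lanes, stripes and threads must all be >= 1")
        if self.block_side is not None and self.block_side % self.lanes != 0:
            raise ConfigError(
                f"block side {self.block_side} is not a multiple of lanes {self.lanes}"
            )
        lane_range(self.delta_width)  # validates

    @property
    def L(self) -> int:
        """Block side in cells."""
        return self.block_side if self.block_side is not None else self.lanes * self.stripes

    @property
    def effective_stripes(self) -> int:
        """Stripe count actually used per block row (L = lanes x this)."""
        return self.L // self.lanes


def align_pairwise(
    reference: str,
    query: str,
    scheme: ScoringScheme | None = None,
    params: EngineParams | None = None,
    reference_id: str = "reference",
    query_id: str = "query",
) -> AlignmentResult:
    """Global alignment of two sequences with the striped/blocked engine.

    The score equals the plain-DP oracle's for every legal (lanes, stripes,
    threads) combination; in traceback mode the CIGAR follows the canonical
    tie-break (diagonal > vertical > horizontal, extension over opening) and
    therefore also matches the oracle's path.
    """
    scheme = scheme or ScoringScheme()
    params = params or EngineParams()
    rc = encode(reference, "reference")
    qc = encode(query, "query")
    n, m = len(rc), len(qc)

    # degenerate shapes: single forced path
    if n == 0 and m == 0:
        return AlignmentResult(0, "" if params.traceback else None,
                               query_id, reference_id, scheme=scheme, params=params)
    if m == 0:
        return AlignmentResult(gap_cost(n, scheme), f"{n}D" if params.traceback else None,
                               query_id, reference_id, scheme=scheme, params=params)
    if n == 0:
        return AlignmentResult(gap_cost(m, scheme), f"{m}I" if params.traceback else None,
                               query_id, reference_id, scheme=scheme, params=params)

    sub = scheme.substitution_matrix()
    o, e = scheme.gap_open, scheme.gap_extend
    S, D = params.lanes, params.effective_stripes
    bounds = lane_range(params.delta_width)
    lane_min, lane_max = bounds if bounds else (0, 0)
    check = bounds is not None
    dirs = np.zeros((n, m), dtype=np.uint8) if params.traceback else None
    plan = partition_matrix(n, m, params.L)

    def block_fn(task: BlockTask, top: BoundaryPacket, left: BoundaryPacket):
        anchor, dH_top, erel_top, dV_left, frel_left = stitch_boundaries(left, top, task)
        h, w = task.shape
        dH_bot = np.empty(w, dtype=np.int64)
        erel_bot = np.empty(w, dtype=np.int64)
        dV_right = np.empty(h, dtype=np.int64)
        frel_right = np.empty(h, dtype=np.int64)
        if dirs is not None:
            dslice = dirs[task.row_start - 1 : task.row_stop - 1,
                          task.col_start - 1 : task.col_stop - 1]
        else:
            dslice = _DUMMY_DIRS
        overflow = np.empty(2, dtype=np.int64)
        _kernels.block_update(
            rc[task.row_start - 1 : task.row_stop - 1],
            qc[task.col_start - 1 : task.col_stop - 1],
            sub, o, e, S, D,
            np.ascontiguousarray(dH_top), np.ascontiguousarray(erel_top),
            np.ascontiguousarray(dV_left), np.ascontiguousarray(frel_left),
            dH_bot, erel_bot, dV_right, frel_right,
            dslice, dirs is not None, lane_min, lane_max, check, overflow,
        )
        if check and overflow[0] >= 0:
            i = task.row_start + int(overflow[0])
            j = task.col_start + int(overflow[1])
            raise LaneOverflowError(
                f"difference value at cell ({i},{j}) exceeds the "
                f"{params.delta_width} lane range; use delta_width='exact'"
            )
        bottom = BoundaryPacket(anchor + int(np.sum(dV_left)), dH_bot, erel_bot)
        right = BoundaryPacket(anchor + int(np.sum(dH_top)), dV_right, frel_right)
        return bottom, right

    final_bottom = execute_ladder(plan, params.threads, block_fn, scheme)
    score = int(final_bottom.absolute()[-1])
    cigar = None
    if params.traceback:
        cigar = traceback_striped(dirs, reference, query, scheme)
    return AlignmentResult(score, cigar, query_id, reference_id,
                           scheme=scheme, params=params)


_DUMMY_DIRS = np.zeros((1, 1), dtype=np.uint8)


def traceback_striped(
    direction_store: np.ndarray | None,
    reference: str,
    query: str,
    scheme: ScoringScheme | None = None,
) -> str:
    """Walk a packed 4-bit direction store back to a CIGAR.

    Codes per cell: bits 0-1 = score source (0 diagonal, 1 vertical gap E,
    2 horizontal gap F), bit 2 = E extends (stay in the vertical gap), bit 3 =
    F extends.  The walk is state-aware, matching the oracle's tie-breaks, so
    the CIGAR is identical to :func:`trapalign.oracle.traceback_pairwise`.
    """
    if direction_store is None:
        raise StateError("traceback requested but no direction store was kept")
    n, m = direction_store.shape
    if n != len(reference) or m != len(query):
        raise StateError("direction store shape does not match the sequences")
    ops: list[str] = []
    i, j = n, m
    state = "M"
    while i > 0 or j > 0:
        if state == "M":
            if i == 0:
                ops.append("I")
                j -= 1
                continue
            if j == 0:
                ops.append("D")
                i -= 1
                continue
            code = int(direction_store[i - 1, j - 1]) & 0b11
            if code == 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif code == 1:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            extend = int(direction_store[i - 1, j - 1]) & 0b100
            i -= 1
            if not extend or i == 0:
                state = "M"
        else:  # F
            ops.append("I")
            extend = int(direction_store[i - 1, j - 1]) & 0b1000
            j -= 1
            if not extend or j == 0:
                state = "M"
    ops.reverse()
    return cigar_to_string(ops)


def dump_delta_rows(rows, stream=None) -> str:
    """Debug dump of a difference row as TSV (cell index, dH, erel)."""
    out = stream or _io.StringIO()
    out.write("cell\tdH\terel\n")
    for p, (dh, er) in enumerate(zip(rows.dH, rows.erel)):
        out.write(f"{p}\t{int(dh)}\t{int(er)}\n")
    return out.getvalue() if stream is None else ""
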