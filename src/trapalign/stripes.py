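"""Difference-recurrence row state, stripe layout and the three-phase row update.

The difference method replaces absolute DP scores with per-cell differences:
``S`` (current cell versus the upper-left diagonal cell), ``dH`` (versus the
left cell), ``dV`` (versus the cell above), plus the gap scores in the same
diagonal-anchored difference form (``Ed``, ``Fd``).  The identities

    dV = S - dH_above        dH = S - dV_left

close the recurrence, and because all differences are bounded by the scoring
constants, narrow integer lanes suffice to store them.

A row of length L = S x D is processed in *striped* order: cell ``p`` lives
in stripe ``p % D`` and lane ``p // D``, so a vector of S lanes advances S
non-adjacent cells at once and only the horizontal dependency needs fixing.
The fix is the Active-F three-phase update (see :func:`compute_striped_row`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ConfigError
from .scoring import NEG_INF, ScoringScheme


@dataclass(frozen=True)
class DeltaCell:
    """The five difference values of one DP cell.

    ``S_val`` is the score difference to the upper-left diagonal cell; ``dH``
    and ``dV`` the differences to the left cell and the cell above; ``Ed``
    and ``Fd`` the vertical/horizontal gap scores in the same diagonal-anchored
    difference form.
    """

    S_val: int
    dH: int
    dV: int
    Ed: int
    Fd: int


def psa_diff_cell(
    Ed: int,
    Fd: int,
    q: int,
    dV_left: int,
    dH_above: int,
    scheme: ScoringScheme | None = None,
) -> DeltaCell:
    """One cell of the pairwise difference recurrence.

    ``Ed`` and ``Fd`` are the cell's incoming gap candidates already expressed
    as differences to the upper-left diagonal cell (formed from the neighbour
    states by :func:`gap_candidates`); ``q`` is the match/mismatch score.
    The cell score is ``S = max(Ed, q, Fd)`` and the outgoing differences
    close via ``dV = S - dH_above`` and ``dH = S - dV_left``.
    """
    s = max(Ed, q, Fd)
    return DeltaCell(S_val=s, dH=s - dV_left, dV=s - dH_above, Ed=Ed, Fd=Fd)


def gap_candidates(
    erel_above: int,
    dH_above: int,
    frel_left: int,
    dV_left: int,
    scheme: ScoringScheme,
) -> tuple[int, int]:
    """Form the diagonal-anchored gap candidates (Ed, Fd) of a cell.

    ``erel_above`` is the vertical-gap state of the cell above relative to its
    own score (E - M); ``frel_left`` likewise for the horizontal gap of the
    left cell.  Opening versus extension resolves as ``max(rel, o) + e`` and
    the result is re-anchored to the diagonal cell via dH_above / dV_left.
    """
    o, e = scheme.gap_open, scheme.gap_extend
    ed = max(erel_above, o) + e + dH_above
    fd = max(frel_left, o) + e + dV_left
    return ed, fd


@dataclass(frozen=True)
class StripeLayout:
    """Farrar mapping of a length-L segment onto S lanes x D stripes."""

    lanes: int  # S
    stripes: int  # D

    def __post_init__(self) -> None:
        if self.lanes < 1 or self.stripes < 1:
            raise ConfigError("lanes and stripes must be >= 1")

    @property
    def length(self) -> int:
        return self.lanes * self.stripes

    def forward(self, p: int) -> tuple[int, int]:
        """cell index -> (stripe, lane)"""
        if not 0 <= p < self.length:
            raise ConfigError(f"cell {p} outside [0, {self.length})")
        return p % self.stripes, p // self.stripes

    def inverse(self, stripe: int, lane: int) -> int:
        """(stripe, lane) -> cell index"""
        p = lane * self.stripes + stripe
        if not (0 <= stripe < self.stripes and 0 <= lane < self.lanes):
            raise ConfigError(f"(stripe={stripe}, lane={lane}) outside layout")
        return p

    def scatter(self, values: np.ndarray) -> np.ndarray:
        """Rearrange a row into (stripes, lanes) striped order."""
        return np.asarray(values).reshape(self.lanes, self.stripes).T

    def gather(self, striped: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`scatter`."""
        return np.asarray(striped).T.reshape(self.length)


def stripe_layout(L: int, S: int, D: int) -> StripeLayout:
    """Build the layout, enforcing L == S x D."""
    if L != S * D:
        raise ConfigError(f"block side {L} != lanes {S} x stripes {D}")
    return StripeLayout(lanes=S, stripes=D)


@dataclass
class DeltaRows:
    """Difference state flowing from one row of a block to the next.

    ``dH`` holds the previous row's horizontal differences for the segment's
    columns; ``erel`` the previous row's vertical-gap state relative to its
    own score (E - M).  ``dv_left`` and ``frel_left`` are the current row's
    left rim: the vertical difference entering from the left neighbour and
    its horizontal-gap state.  After :func:`compute_striped_row` the same
    fields describe the freshly computed row, and ``dv_right``/``frel_right``
    carry the state leaving the segment's right edge.
    """

    dH: np.ndarray
    erel: np.ndarray
    dv_left: int = 0
    frel_left: int = NEG_INF
    dv_right: int = 0
    frel_right: int = NEG_INF

    def copy(self) -> "DeltaRows":
        return DeltaRows(self.dH.copy(), self.erel.copy(), self.dv_left,
                         self.frel_left, self.dv_right, self.frel_right)


def _q_row(reference_base: str, query_segment: str, scheme: ScoringScheme) -> np.ndarray:
    """Per-column match/mismatch scores of one row."""
    from .scoring import encode

    rcode = int(encode(reference_base, "reference base")[0])
    qcodes = encode(query_segment, "query segment")
    return scheme.substitution_matrix()[rcode][qcodes]


def sequential_row(
    rows: DeltaRows,
    reference_base: str,
    query_segment: str,
    scheme: ScoringScheme,
) -> DeltaRows:
    """Cell-by-cell evaluation of one row via :func:`psa_diff_cell`.

    The plain sequential reference the striped kernel is verified against.
    """
    q_row = _q_row(reference_base, query_segment, scheme)
    w = len(q_row)
    dH_new = np.empty(w, dtype=np.int64)
    erel_new = np.empty(w, dtype=np.int64)
    dv = int(rows.dv_left)
    frel = int(rows.frel_left)
    for p in range(w):
        ed, fd = gap_candidates(int(rows.erel[p]), int(rows.dH[p]), frel, dv, scheme)
        cell = psa_diff_cell(ed, fd, int(q_row[p]), dv, int(rows.dH[p]), scheme)
        dH_new[p] = cell.dH
        erel_new[p] = ed - cell.S_val
        frel = fd - cell.S_val
        dv = cell.dV
    return DeltaRows(dH_new, erel_new, rows.dv_left, rows.frel_left, dv, frel)


def _row_frame(
    rows: DeltaRows, q_row: np.ndarray, layout: StripeLayout, scheme: ScoringScheme
) -> tuple[np.ndarray, np.ndarray, int, int, np.ndarray, np.ndarray]:
    """Run the striped kernel on one row; return the row-relative frame.

    The frame is anchored at the segment's upper-left outer corner: ``P`` is
    the previous row's scores (length w+1, P[0] = corner), ``B`` the combined
    diagonal/vertical candidates padded to the layout length, ``H``/``Fp`` the
    computed row and horizontal-gap scores.
    """
    w = len(q_row)
    L = layout.length
    if w > L:
        raise ConfigError(f"segment of {w} cells exceeds layout length {L}")
    o, e = scheme.gap_open, scheme.gap_extend
    P = np.empty(w + 1, dtype=np.int64)
    P[0] = 0
    np.cumsum(rows.dH, out=P[1:])
    ecand = np.maximum(rows.erel.astype(np.int64), o) + e
    B = np.full(L, _kernels.NEG, dtype=np.int64)
    B[:w] = np.maximum(P[:w] + np.asarray(q_row, dtype=np.int64), P[1:] + ecand)
    lm = int(rows.dv_left)
    fb = int(rows.frel_left) + lm
    H = np.empty(L, dtype=np.int64)
    Fp = np.empty(L, dtype=np.int64)
    _kernels.striped_row(B, lm, fb, o, e, layout.lanes, layout.stripes, H, Fp)
    return P, B, lm, fb, H, Fp


def compute_striped_row(
    rows: DeltaRows,
    reference_base: str,
    query_segment: str,
    layout: StripeLayout,
    scheme: ScoringScheme,
) -> DeltaRows:
    """Three-phase striped update of one row (Active-F).

    Phase 1 runs the stripes once with the horizontal carry fed stripe to
    stripe, which leaves the first cell of every lane's run correct; phase 2
    sweeps the final carry once, updating only lanes whose horizontal score
    was breached; phase 3 reruns the stripes from the corrected carry.  The
    result equals :func:`sequential_row` cell for cell.

    The query segment may be shorter than the layout; missing cells are
    padded with dummy symbols that score -inf against everything and cannot
    enter an optimal path.
    """
    q_row = _q_row(reference_base, query_segment, scheme)
    w = len(q_row)
    P, _B, lm, _fb, H, Fp = _row_frame(rows, q_row, layout, scheme)
    ecand = np.maximum(rows.erel.astype(np.int64), scheme.gap_open) + scheme.gap_extend
    dH_new = np.empty(w, dtype=np.int64)
    dH_new[0] = H[0] - lm
    np.subtract(H[1:w], H[: w - 1], out=dH_new[1:])
    erel_new = ecand + P[1:] - H[:w]
    return DeltaRows(
        dH_new,
        erel_new,
        rows.dv_left,
        rows.frel_left,
        int(H[w - 1] - P[w]),
        int(Fp[w - 1] - H[w - 1]),
    )


def active_f_breaches(
    rows: DeltaRows,
    reference_base: str,
    query_segment: str,
    layout: StripeLayout,
    scheme: ScoringScheme,
) -> int:
    """Verification pass: breached cells remaining after the three phases.

    Reruns the striped update, then re-derives the row's horizontal chain
    sequentially and counts cells where the exact candidate strictly exceeds
    the striped result.  Zero after a correct Active-F update.
    """
    q_row = _q_row(reference_base, query_segment, scheme)
    w = len(q_row)
    B, lm, fb, H, Fp = _row_frame(rows, q_row, layout, scheme)[1:]
    o, e = scheme.gap_open, scheme.gap_extend
    return int(_kernels.row_breach_count(B, lm, fb, o, e, H, Fp, w))


def reconstruct_absolute(anchor: int, diffs) -> list[int]:
    """Prefix-sum a run of differences onto an absolute anchor score."""
    out = []
    acc = int(anchor)
    for d in diffs:
        acc += int(d)
        out.append(acc)
    return out


def lane_range(delta_width: str) -> tuple[int, int] | None:
    """Value range implied by a lane width; None means unbounded (exact)."""
    if delta_width == "exact":
        return None
    if delta_width == "int8":
        return (-128, 127)
    raise ConfigError(f"unknown delta_width {delta_width!r} (use 'exact' or 'int8')")
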