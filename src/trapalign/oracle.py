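"""Plain absolute-score global alignment: the ground-truth oracle.

This module is the trusted, unoptimized implementation of global affine-gap
alignment (Needleman-Wunsch-Gotoh) in both its pairwise and partial-order
graph forms.  Every optimized engine in the package is verified against it;
it is also the traceback source in oracle mode.

Three matrices are kept: ``M`` (best score ending at a cell), ``E`` (best
score ending in a vertical gap, i.e. consuming reference only) and ``F``
(best score ending in a horizontal gap, consuming query only).  Row/column 0
carry the global boundary: ``M[i][0] = gap_cost(i)``, ``M[0][j] =
gap_cost(j)``, with the inapplicable gap matrix set to the -inf sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from . import _kernels
from .cigar import cigar_to_string
from .errors import InputError, InternalError, ResourceError
from .scoring import NEG_INF, ScoringScheme, encode, is_neg_inf

if TYPE_CHECKING:  # pragma: no cover
    from .poa import PoaGraph

#: dense-matrix size cap per side; beyond this the striped engine is the tool
ORACLE_SIZE_CAP = 100_000


@dataclass
class DpMatrices:
    """The three filled score matrices of a pairwise global DP."""

    M: np.ndarray
    E: np.ndarray
    F: np.ndarray
    n: int  # reference length (rows)
    m: int  # query length (columns)

    @property
    def score(self) -> int:
        return int(self.M[self.n, self.m])


def _check_cap(n: int, m: int) -> None:
    if n > ORACLE_SIZE_CAP or m > ORACLE_SIZE_CAP:
        raise ResourceError(
            f"dense oracle refuses {n} x {m}; use the striped engine "
            f"(cap {ORACLE_SIZE_CAP} per side)"
        )


def global_affine_dp(
    reference: str, query: str, scheme: ScoringScheme | None = None
) -> DpMatrices:
    """Fill the full M/E/F matrices for a global pairwise alignment."""
    scheme = scheme or ScoringScheme()
    rc = encode(reference, "reference")
    qc = encode(query, "query")
    n, m = len(rc), len(qc)
    _check_cap(n, m)
    M = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.empty((n + 1, m + 1), dtype=np.int64)
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    _kernels.gotoh_fill(rc, qc, scheme.substitution_matrix(),
                        scheme.gap_open, scheme.gap_extend, M, E, F)
    return DpMatrices(M, E, F, n, m)


def global_affine_score(
    reference: str, query: str, scheme: ScoringScheme | None = None
) -> int:
    """Optimal global alignment score (matrices are not retained)."""
    return global_affine_dp(reference, query, scheme).score


def traceback_pairwise(
    dp: DpMatrices, reference: str, query: str, scheme: ScoringScheme | None = None
) -> str:
    """One optimal global path as a CIGAR over {M, I, D}.

    State-aware: while inside E (vertical run) or F (horizontal run) the walk
    stays in the gap matrix as long as its extension case holds, so affine
    gaps are traced as single runs.  Tie-break: diagonal over vertical over
    horizontal; within a gap matrix, extension over opening.  D consumes
    reference, I consumes query.
    """
    scheme = scheme or ScoringScheme()
    if dp.n != len(reference) or dp.m != len(query):
        raise InternalError("DP matrices do not match the sequences")
    o, e = scheme.gap_open, scheme.gap_extend
    sub = scheme.substitution_matrix()
    rc = encode(reference, "reference")
    qc = encode(query, "query")
    M, E, F = dp.M, dp.E, dp.F
    ops: list[str] = []
    i, j = dp.n, dp.m
    state = "M"
    while i > 0 or j > 0:
        if state == "M":
            if i == 0:
                ops.append("I")
                j -= 1
            elif j == 0:
                ops.append("D")
                i -= 1
            elif M[i, j] == M[i - 1, j - 1] + sub[rc[i - 1], qc[j - 1]]:
                ops.append("M")
                i -= 1
                j -= 1
            elif M[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if i > 1 and E[i, j] == E[i - 1, j] + e:
                i -= 1
            else:
                i -= 1
                state = "M"
        else:  # F
            ops.append("I")
            if j > 1 and F[i, j] == F[i, j - 1] + e:
                j -= 1
            else:
                j -= 1
                state = "M"
    ops.reverse()
    return cigar_to_string(ops)


# ---------------------------------------------------------------------------
# Partial-order graph oracle
# ---------------------------------------------------------------------------

def poa_reference_align(
    graph: "PoaGraph", query: str, scheme: ScoringScheme | None = None
) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Absolute-score global alignment of ``query`` against a POA graph.

    The pairwise recurrence generalizes to the DAG: a node's diagonal and
    vertical candidates range over all its predecessors (a virtual source
    precedes every head node), the horizontal candidate runs along the query
    inside the node's row.  The alignment is global: it starts at the virtual
    source with column 0 and ends at the best out-degree-0 node with the
    full query consumed; terminal gaps are charged.

    Returns ``(score, path)`` where path is a list of
    ``(node id | None, query index | None)`` pairs: both set for an aligned
    pair, query index None for a deletion (node skipped by the query), node
    None for an insertion.
    """
    scheme = scheme or ScoringScheme()
    if not query:
        raise InputError("query must be non-empty")
    qc = encode(query, "query")
    m = len(qc)
    o, e = scheme.gap_open, scheme.gap_extend
    sub = scheme.substitution_matrix()

    order = graph.topological_order()  # raises InputError on cycles
    rank_of = {nid: r + 1 for r, nid in enumerate(order)}
    nn = len(order)
    # predecessor ranks; 0 is the virtual source
    preds: list[list[int]] = [[]]
    bases = np.zeros(nn + 1, dtype=np.uint8)
    for r, nid in enumerate(order, start=1):
        node = graph.nodes[nid]
        bases[r] = node.code
        ps = sorted(rank_of[p] for p in node.in_edges)
        preds.append(ps if ps else [0])

    M = np.full((nn + 1, m + 1), NEG_INF, dtype=np.int64)
    E = np.full((nn + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((nn + 1, m + 1), NEG_INF, dtype=np.int64)
    M[0, 0] = 0
    for j in range(1, m + 1):
        F[0, j] = o + j * e
        M[0, j] = F[0, j]
    for v in range(1, nn + 1):
        ev0 = max(max(E[p, 0], M[p, 0] + o) for p in preds[v]) + e
        E[v, 0] = ev0
        M[v, 0] = ev0
        qrow = sub[bases[v]]
        for j in range(1, m + 1):
            ev = max(max(E[p, j], M[p, j] + o) for p in preds[v]) + e
            dv = max(M[p, j - 1] for p in preds[v]) + qrow[qc[j - 1]]
            fv = max(F[v, j - 1] + e, M[v, j - 1] + o + e)
            E[v, j] = ev
            F[v, j] = fv
            M[v, j] = max(ev, fv, dv)

    sinks = [rank_of[nid] for nid in order if not graph.nodes[nid].out_edges]
    sinks.sort()
    best = max(sinks, key=lambda v: (M[v, m], -v))
    score = int(M[best, m])

    # traceback: diagonal > vertical > horizontal; among predecessors lowest
    # topological rank wins; within gap matrices extension over opening.
    path: list[tuple[int | None, int | None]] = []
    v, j, state = best, m, "M"
    node_ids = [None] + list(order)
    while v != 0 or j != 0:
        if state == "M":
            if v == 0:
                path.append((None, j - 1))
                j -= 1
                continue
            moved = False
            if j > 0:
                tgt = M[v, j] - sub[bases[v], qc[j - 1]]
                for p in preds[v]:
                    if M[p, j - 1] == tgt:
                        path.append((node_ids[v], j - 1))
                        v, j = p, j - 1
                        moved = True
                        break
            if moved:
                continue
            if M[v, j] == E[v, j]:
                state = "E"
            elif j > 0 and M[v, j] == F[v, j]:
                state = "F"
            else:  # pragma: no cover - would indicate a fill bug
                raise InternalError("graph traceback stuck")
        elif state == "E":
            path.append((node_ids[v], None))
            tgt = E[v, j] - e
            nxt = None
            for p in preds[v]:
                if E[p, j] == tgt and not is_neg_inf(E[p, j]):
                    nxt, nstate = p, "E"
                    break
            if nxt is None:
                for p in preds[v]:
                    if M[p, j] + o == tgt:
                        nxt, nstate = p, "M"
                        break
            if nxt is None:  # pragma: no cover
                raise InternalError("graph traceback stuck in E")
            v, state = nxt, nstate
        else:  # F
            path.append((None, j - 1))
            if j > 1 and F[v, j] == F[v, j - 1] + e:
                j -= 1
            else:
                j -= 1
                state = "M"
    path.reverse()
    return score, path
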