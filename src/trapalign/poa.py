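"""Partial-order alignment: graph construction, graph DP, fusion, MSA rows.

A partial-order graph represents a growing multiple alignment as a DAG of
bases: each node is one base, edges record which sequences run between two
bases (weights are traversal counts), and *aligned groups* link nodes that
occupy the same alignment column with different bases.  New sequences are
aligned against the graph with the same difference/stripe machinery as the
pairwise engine — the only change is that a cell's diagonal and vertical
candidates range over every predecessor node — and then fused back in.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import InputError, InternalError
from .scoring import NEG_INF, ScoringScheme, encode, is_neg_inf

# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------


@dataclass
class PoaNode:
    """One base of the partial-order graph."""

    id: int
    base: str
    code: int
    in_edges: dict[int, int] = field(default_factory=dict)  # pred id -> weight
    out_edges: dict[int, int] = field(default_factory=dict)  # succ id -> weight
    aligned_ids: set[int] = field(default_factory=set)
    members: set[tuple[int, int]] = field(default_factory=set)  # (seq idx, position)


class PoaGraph:
    """DAG of bases with per-node sequence membership and aligned groups."""

    def __init__(self) -> None:
        self.nodes: dict[int, PoaNode] = {}
        self.seq_starts: dict[int, int] = {}
        self.n_sequences: int = 0
        self._next_id: int = 0
        self._order: list[int] | None = None

    # -- construction -------------------------------------------------------

    def add_node(self, base: str) -> PoaNode:
        code = int(encode(base, "base")[0])
        node = PoaNode(self._next_id, base.upper(), code)
        self.nodes[node.id] = node
        self._next_id += 1
        self._order = None
        return node

    def add_edge(self, u: int, v: int, weight: int = 1) -> None:
        if u == v:
            raise InputError(f"self-edge on node {u}")
        self.nodes[u].out_edges[v] = self.nodes[u].out_edges.get(v, 0) + weight
        self.nodes[v].in_edges[u] = self.nodes[v].in_edges.get(u, 0) + weight
        self._order = None

    # -- queries --------------------------------------------------------------

    def heads(self) -> list[int]:
        return sorted(nid for nid, n in self.nodes.items() if not n.in_edges)

    def sinks(self) -> list[int]:
        return sorted(nid for nid, n in self.nodes.items() if not n.out_edges)

    def topological_order(self) -> list[int]:
        """Group-aware topological order with a stable tie-break by node id.

        Kahn's algorithm, modified so that the nodes of an aligned group are
        emitted consecutively (a group is flushed once every member is
        ready).  Keeping groups adjacent makes MSA column assignment
        monotone along every member sequence; for graphs without aligned
        groups this is plain Kahn with a min-id heap.  Every engine sees the
        same linearization.  Raises :class:`InputError` naming a cycle
        witness if the graph is cyclic.
        """
        if self._order is not None:
            return self._order
        indeg = {nid: len(n.in_edges) for nid, n in self.nodes.items()}
        ready = [nid for nid, d in indeg.items() if d == 0]
        heapq.heapify(ready)
        order: list[int] = []
        done: set[int] = set()

        def emit(nid: int) -> None:
            order.append(nid)
            done.add(nid)
            for succ in self.nodes[nid].out_edges:
                indeg[succ] -= 1
                if indeg[succ] == 0:
                    heapq.heappush(ready, succ)

        while ready:
            nid = heapq.heappop(ready)
            if nid in done:
                continue
            group = self.aligned_group(nid)
            if any(indeg[g] > 0 for g in group):
                # the group flushes when its last member becomes ready
                continue
            for gid in sorted(group):
                if gid not in done:
                    emit(gid)
        if len(order) != len(self.nodes):
            witness = sorted(nid for nid in self.nodes if nid not in done)
            raise InputError(f"graph contains a cycle through nodes {witness[:8]}")
        self._order = order
        return order

    def spell(self, seq_index: int) -> str:
        """Reconstruct a member sequence from node memberships."""
        hits = []
        for node in self.nodes.values():
            for s, pos in node.members:
                if s == seq_index:
                    hits.append((pos, node.base))
        hits.sort()
        if [p for p, _ in hits] != list(range(len(hits))):
            raise InternalError(f"sequence {seq_index} membership has gaps")
        return "".join(b for _, b in hits)

    def aligned_group(self, nid: int) -> set[int]:
        """The node itself plus everything recorded as aligned to it."""
        return {nid} | self.nodes[nid].aligned_ids

    def to_dot(self) -> str:
        """Graphviz dump for inspection."""
        lines = ["digraph poa {"]
        for nid in self.topological_order():
            node = self.nodes[nid]
            lines.append(f'  n{nid} [label="{node.base}({nid})"];')
            for succ, wt in sorted(node.out_edges.items()):
                lines.append(f"  n{nid} -> n{succ} [label={wt}];")
            for aid in sorted(node.aligned_ids):
                if aid > nid:
                    lines.append(f"  n{nid} -> n{aid} [style=dashed, dir=none];")
        lines.append("}")
        return "\n".join(lines)


def graph_from_sequence(seq: str, seq_index: int = 0) -> PoaGraph:
    """Linear chain graph of a single sequence: one node per base."""
    if not seq:
        raise InputError("cannot build a graph from an empty sequence")
    encode(seq, "sequence")
    graph = PoaGraph()
    prev = None
    for pos, base in enumerate(seq.upper()):
        node = graph.add_node(base)
        node.members.add((seq_index, pos))
        if prev is not None:
            graph.add_edge(prev.id, node.id)
        else:
            graph.seq_starts[seq_index] = node.id
        prev = node
    graph.n_sequences = max(graph.n_sequences, seq_index + 1)
    return graph


def topological_order(graph: PoaGraph) -> list[int]:
    """Module-level convenience over :meth:`PoaGraph.topological_order`."""
    return graph.topological_order()


# ---------------------------------------------------------------------------
# MSA difference recurrence (per-cell form)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MsaPredState:
    """Incoming difference state of one predecessor ``x`` at a cell.

    ``Ed`` is the vertical-gap candidate entering via x, ``Fd`` the horizontal
    candidate, both anchored to x's diagonal cell score M(x, j-1); ``dV_left``
    is the left cell's vertical difference against x; ``dH_above`` is x's own
    horizontal difference at this column.
    """

    Ed: int
    Fd: int
    dV_left: int
    dH_above: int


@dataclass(frozen=True)
class MsaDeltaCell:
    """Outputs of one MSA difference cell.

    ``dH`` is the (unique) horizontal difference of the cell; ``Ed`` the
    outgoing vertical-gap candidate for successor rows, anchored at the left
    cell's score; ``Fd_by_pred`` / ``dV_by_pred`` the outgoing horizontal
    candidates and vertical differences, one per predecessor.
    """

    dH: int
    Ed: int
    Fd_by_pred: tuple[int, ...]
    dV_by_pred: tuple[int, ...]


def msa_diff_cell(
    preds: list[MsaPredState], q: int, scheme: ScoringScheme | None = None
) -> MsaDeltaCell:
    """One cell of the MSA difference recurrence.

    The horizontal difference is taken directly as the maximum over
    predecessors of the re-anchored cell score; the per-predecessor vertical
    differences and gap candidates then close the recurrence:

        dH     = max_x( max(Ed_x, q, Fd_x) - dV_left_x )
        Ed     = max( max_x(Ed_x + e - dV_left_x), dH + o + e )
        Fd_x   = max( Fd_x + e, dH + o + e + dV_left_x ) - dH_above_x
        dV_x   = dH + dV_left_x - dH_above_x

    With a single predecessor this reduces exactly to the pairwise cell.
    """
    scheme = scheme or ScoringScheme()
    if not preds:
        raise InputError("at least one predecessor state is required")
    o, e = scheme.gap_open, scheme.gap_extend
    dH = max(max(p.Ed, q, p.Fd) - p.dV_left for p in preds)
    Ed = max(max(p.Ed + e - p.dV_left for p in preds), dH + o + e)
    Fd_out = tuple(
        max(p.Fd + e, dH + o + e + p.dV_left) - p.dH_above for p in preds
    )
    dV_out = tuple(dH + p.dV_left - p.dH_above for p in preds)
    return MsaDeltaCell(dH, Ed, Fd_out, dV_out)


# ---------------------------------------------------------------------------
# graph alignment engine
# ---------------------------------------------------------------------------


def align_to_graph(
    graph: PoaGraph,
    query: str,
    scheme: ScoringScheme | None = None,
    params=None,
) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Global alignment of a query against the graph (difference engine).

    Node rows are processed in topological order.  For each node the diagonal
    and vertical candidates are maximized over all predecessors (the MSA
    generalization of the pairwise recurrence); the horizontal chain along the
    query is then resolved with the same three-phase striped row update as
    the pairwise engine.  Rows span the full query width (stripe count grows
    with the query; boundary-crossing nodes keep full-row state), so lane and
    stripe settings influence only the layout, never the result.

    Returns ``(score, path)`` with the same path convention and canonical
    tie-breaks as :func:`trapalign.oracle.poa_reference_align`; the score is
    identical to the oracle's for every legal parameter choice.
    """
    from .engine import EngineParams  # local import to avoid a cycle

    scheme = scheme or ScoringScheme()
    params = params or EngineParams()
    if not query:
        raise InputError("query must be non-empty")
    qc = encode(query, "query")
    m = len(qc)
    o, e = scheme.gap_open, scheme.gap_extend
    sub = scheme.substitution_matrix()

    order = graph.topological_order()
    nn = len(order)
    rank_of = {nid: r + 1 for r, nid in enumerate(order)}
    preds: list[list[int]] = [[]]
    bases = np.zeros(nn + 1, dtype=np.uint8)
    for r, nid in enumerate(order, start=1):
        node = graph.nodes[nid]
        bases[r] = node.code
        ps = sorted(rank_of[p] for p in node.in_edges)
        preds.append(ps if ps else [0])

    S = params.lanes
    D = max(1, -(-m // S))
    L = S * D

    M = np.full((nn + 1, m + 1), NEG_INF, dtype=np.int64)
    E = np.full((nn + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((nn + 1, m + 1), NEG_INF, dtype=np.int64)
    M[0, 0] = 0
    js = np.arange(1, m + 1, dtype=np.int64)
    F[0, 1:] = o + js * e
    M[0, 1:] = F[0, 1:]

    B = np.full(L, _kernels.NEG, dtype=np.int64)
    H = np.empty(L, dtype=np.int64)
    Fp = np.empty(L, dtype=np.int64)
    for v in range(1, nn + 1):
        pv = preds[v]
        if len(pv) == 1:
            p = pv[0]
            ev = np.maximum(E[p], M[p] + o) + e
            diag = M[p, :m]
        else:
            ev = np.maximum(E[pv[0]], M[pv[0]] + o)
            diag = M[pv[0], :m].copy()
            for p in pv[1:]:
                np.maximum(ev, np.maximum(E[p], M[p] + o), out=ev)
                np.maximum(diag, M[p, :m], out=diag)
            ev = ev + e
        qrow = sub[bases[v]][qc]
        B[:m] = np.maximum(diag + qrow, ev[1:])
        _kernels.striped_row(B, int(ev[0]), NEG_INF, o, e, S, D, H, Fp)
        M[v, 0] = ev[0]
        M[v, 1:] = H[:m]
        E[v] = ev
        F[v, 1:] = Fp[:m]

    sinks = sorted(rank_of[nid] for nid in order if not graph.nodes[nid].out_edges)
    best = max(sinks, key=lambda v: (M[v, m], -v))
    score = int(M[best, m])
    path = _graph_traceback(graph, order, preds, bases, qc, M, E, F, best, scheme, sub)
    return score, path


def _graph_traceback(graph, order, preds, bases, qc, M, E, F, best, scheme, sub):
    """Shared affine-correct walk over graph DP rows (canonical tie-breaks)."""
    o, e = scheme.gap_open, scheme.gap_extend
    m = len(qc)
    node_ids = [None] + list(order)
    path: list[tuple[int | None, int | None]] = []
    v, j, state = best, m, "M"
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
                    if M[p, j - 1] == tgt and not is_neg_inf(int(M[p, j - 1])):
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
            nxt = nstate = None
            for p in preds[v]:
                if E[p, j] == tgt and not is_neg_inf(int(E[p, j])):
                    nxt, nstate = p, "E"
                    break
            if nxt is None:
                for p in preds[v]:
                    if M[p, j] + o == tgt and not is_neg_inf(int(M[p, j])):
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
    return path


# ---------------------------------------------------------------------------
# fusion and MSA
# ---------------------------------------------------------------------------


def fuse_alignment(
    graph: PoaGraph,
    query: str,
    path: list[tuple[int | None, int | None]],
    seq_index: int,
) -> PoaGraph:
    """Thread an aligned query into the graph (in place; also returned).

    Matched positions with an equal base merge into the existing node;
    mismatched positions merge into an aligned-group partner with the same
    base when one exists, otherwise they become a new node cross-linked into
    the group; insertions become new chain nodes.  Deletions (query skips a
    node) leave the graph untouched.  The member sequence of ``seq_index``
    spells the query exactly afterwards.
    """
    query = query.upper()
    consumed = [qpos for _, qpos in path if qpos is not None]
    if consumed != list(range(len(query))):
        raise InternalError("path does not consume the query exactly once")
    prev: PoaNode | None = None
    for nid, qpos in path:
        if qpos is None:
            continue  # deletion: query does not traverse this node
        base = query[qpos]
        if nid is None:
            node = graph.add_node(base)
        else:
            anchor = graph.nodes[nid]
            if anchor.base == base:
                node = anchor
            else:
                node = None
                for aid in sorted(anchor.aligned_ids):
                    if graph.nodes[aid].base == base:
                        node = graph.nodes[aid]
                        break
                if node is None:
                    node = graph.add_node(base)
                    group = graph.aligned_group(anchor.id)
                    node.aligned_ids |= group
                    for gid in group:
                        graph.nodes[gid].aligned_ids.add(node.id)
        node.members.add((seq_index, qpos))
        if prev is None:
            graph.seq_starts[seq_index] = node.id
        else:
            graph.add_edge(prev.id, node.id)
        prev = node
    graph.n_sequences = max(graph.n_sequences, seq_index + 1)
    graph.topological_order()  # raises if fusion ever broke acyclicity
    return graph


def msa_rows_from_graph(graph: PoaGraph) -> list[str]:
    """One gapped row per member sequence; aligned groups share a column.

    Columns follow the canonical topological order (a group takes the column
    of its first member in that order).  Removing gaps from row s reproduces
    input sequence s exactly.
    """
    order = graph.topological_order()
    col_of: dict[int, int] = {}
    ncols = 0
    for nid in order:
        if nid in col_of:
            continue
        for gid in graph.aligned_group(nid):
            col_of[gid] = ncols
        ncols += 1
    nseq = graph.n_sequences
    rows = [["-"] * ncols for _ in range(nseq)]
    last_col = [-1] * nseq
    per_seq: list[list[tuple[int, int]]] = [[] for _ in range(nseq)]
    for nid in order:
        node = graph.nodes[nid]
        for s, pos in node.members:
            per_seq[s].append((pos, nid))
    for s in range(nseq):
        for pos, nid in sorted(per_seq[s]):
            col = col_of[nid]
            if col <= last_col[s]:
                raise InternalError(
                    f"sequence {s} visits column {col} after {last_col[s]}"
                )
            rows[s][col] = graph.nodes[nid].base
            last_col[s] = col
    return ["".join(r) for r in rows]


def msa(
    sequences: list[str],
    scheme: ScoringScheme | None = None,
    params=None,
) -> tuple[list[str], PoaGraph]:
    """Progressive partial-order MSA in input order.

    Builds the graph from the first sequence, then aligns and fuses each
    subsequent sequence.  Deterministic for a fixed input order and
    parameters.  Returns the gapped rows (one per input, order preserved)
    and the final graph.
    """
    scheme = scheme or ScoringScheme()
    if not sequences:
        raise InputError("at least one sequence is required")
    for k, s in enumerate(sequences):
        if not s:
            raise InputError(f"sequence {k} is empty")
    graph = graph_from_sequence(sequences[0], 0)
    for k, seq in enumerate(sequences[1:], start=1):
        _score, path = align_to_graph(graph, seq, scheme, params)
        fuse_alignment(graph, seq, path, k)
    return msa_rows_from_graph(graph), graph
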