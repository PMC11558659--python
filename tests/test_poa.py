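"""Partial-order graph engine: construction, alignment, fusion, MSA rows."""

import networkx as nx
import numpy as np
import pytest

from trapalign.engine import EngineParams, align_pairwise
from trapalign.errors import InputError
from trapalign.oracle import poa_reference_align
from trapalign.poa import (
    MsaPredState,
    align_to_graph,
    fuse_alignment,
    graph_from_sequence,
    msa,
    msa_diff_cell,
    msa_rows_from_graph,
    topological_order,
)
from trapalign.scoring import NEG_INF
from trapalign.simulate import MutationModel, dataset, random_sequence
from trapalign.stripes import gap_candidates, psa_diff_cell


# --- graph construction -------------------------------------------------------


def test_graph_from_sequence_chain():
    g = graph_from_sequence("ACGT")
    assert len(g.nodes) == 4
    assert sum(len(n.out_edges) for n in g.nodes.values()) == 3
    assert g.topological_order() == sorted(g.nodes)
    assert g.spell(0) == "ACGT"


def test_graph_single_base():
    g = graph_from_sequence("A")
    assert len(g.nodes) == 1
    assert not g.nodes[0].out_edges


def test_graph_rejects_empty():
    with pytest.raises(InputError):
        graph_from_sequence("")


def test_topological_order_validates_against_networkx(scheme):
    rng = np.random.default_rng(31)
    for t in range(30):
        seqs = dataset(int(rng.integers(2, 5)), int(rng.integers(5, 40)),
                       MutationModel(0.2, 0.08, 0.08, 0.7, seed=t))
        _, g = msa(seqs, scheme)
        order = topological_order(g)
        nxg = nx.DiGraph()
        nxg.add_nodes_from(g.nodes)
        for nid, node in g.nodes.items():
            nxg.add_edges_from((nid, s) for s in node.out_edges)
        assert nx.is_directed_acyclic_graph(nxg)
        pos = {nid: k for k, nid in enumerate(order)}
        assert len(order) == len(g.nodes)
        assert all(pos[u] < pos[v] for u, v in nxg.edges)


def test_topological_order_fork_join():
    g = graph_from_sequence("ACGT", 0)
    _, path = align_to_graph(g, "AGGT")
    fuse_alignment(g, "AGGT", path, 1)
    order = g.topological_order()
    pos = {nid: k for k, nid in enumerate(order)}
    c = next(n for n in g.nodes.values() if n.base == "C")
    g2 = next(n for n in g.nodes.values() if n.base == "G" and n.aligned_ids)
    a = next(n for n in g.nodes.values() if n.base == "A" and not n.in_edges)
    join = g.nodes[next(iter(c.out_edges))]
    assert pos[a.id] < pos[c.id] < pos[join.id]
    assert pos[a.id] < pos[g2.id] < pos[join.id]


def test_cycle_reported_with_witness():
    g = graph_from_sequence("ACGT")
    g.add_edge(3, 0)
    with pytest.raises(InputError, match="cycle"):
        g.topological_order()


# --- MSA difference cell -------------------------------------------------------


def test_msa_cell_single_pred_reduces_to_pairwise_cell(scheme):
    rng = np.random.default_rng(42)
    o, e = scheme.gap_open, scheme.gap_extend
    for _ in range(200):
        erel = int(NEG_INF if rng.random() < 0.3 else rng.integers(-12, -3))
        frel = int(NEG_INF if rng.random() < 0.3 else rng.integers(-12, -3))
        dv_left = int(rng.integers(-6, 3))
        dh_above = int(rng.integers(-6, 3))
        q = int(rng.choice([2, -3]))
        ed, fd = gap_candidates(erel, dh_above, frel, dv_left, scheme)
        pair = psa_diff_cell(ed, fd, q, dv_left, dh_above, scheme)
        cell = msa_diff_cell([MsaPredState(ed, fd, dv_left, dh_above)], q, scheme)
        assert cell.dH == pair.dH
        assert cell.dV_by_pred[0] == pair.dV
        # outgoing candidates agree with the pairwise candidate formation
        erel_next = ed - pair.S_val
        frel_next = fd - pair.S_val
        ed_next, fd_next = gap_candidates(erel_next, pair.dH, frel_next, pair.dV, scheme)
        assert cell.Ed == ed_next
        assert cell.Fd_by_pred[0] == fd_next


def test_msa_cell_duplicate_preds_equal_single(scheme):
    st = MsaPredState(-6, -7, 0, 1)
    one = msa_diff_cell([st], 2, scheme)
    two = msa_diff_cell([st, st], 2, scheme)
    assert (two.dH, two.Ed) == (one.dH, one.Ed)
    assert set(two.Fd_by_pred) == set(one.Fd_by_pred)
    assert set(two.dV_by_pred) == set(one.dV_by_pred)


def test_msa_cell_requires_predecessor(scheme):
    with pytest.raises(InputError):
        msa_diff_cell([], 2, scheme)


# --- graph alignment engine ----------------------------------------------------


def test_align_to_graph_identity(scheme):
    g = graph_from_sequence("ACGT")
    score, path = align_to_graph(g, "ACGT", scheme)
    assert score == 8
    assert path == [(0, 0), (1, 1), (2, 2), (3, 3)]


def test_linear_graph_consistent_with_pairwise(scheme):
    rng = np.random.default_rng(13)
    for t in range(100):
        a = random_sequence(int(rng.integers(1, 150)), 5 * t)
        b = random_sequence(int(rng.integers(1, 150)), 5 * t + 1)
        g = graph_from_sequence(a)
        sg, _ = align_to_graph(g, b, scheme)
        assert sg == align_pairwise(a, b, scheme).score


def test_align_to_graph_matches_oracle_on_fused_graphs(scheme):
    rng = np.random.default_rng(14)
    for t in range(40):
        seqs = dataset(int(rng.integers(2, 6)), int(rng.integers(10, 100)),
                       MutationModel(0.1, 0.05, 0.05, 0.7, seed=500 + t))
        g = graph_from_sequence(seqs[0], 0)
        for k, s in enumerate(seqs[1:-1], start=1):
            _, p = align_to_graph(g, s, scheme)
            fuse_alignment(g, s, p, k)
        q = seqs[-1]
        assert align_to_graph(g, q, scheme)[0] == poa_reference_align(g, q, scheme)[0]


def test_align_to_graph_param_invariance(scheme):
    seqs = dataset(3, 80, MutationModel(seed=9))
    g = graph_from_sequence(seqs[0], 0)
    _, p = align_to_graph(g, seqs[1], scheme)
    fuse_alignment(g, seqs[1], p, 1)
    results = {
        align_to_graph(g, seqs[2], scheme, EngineParams(lanes=S, stripes=D, threads=T))[0]
        for S in (4, 8, 16) for D in (1, 4) for T in (1, 4)
    }
    assert len(results) == 1


# --- fusion ---------------------------------------------------------------------


def test_fuse_identical_sequence_merges_fully(scheme):
    g = graph_from_sequence("ACGT", 0)
    _, path = align_to_graph(g, "ACGT", scheme)
    fuse_alignment(g, "ACGT", path, 1)
    assert len(g.nodes) == 4
    weights = [w for n in g.nodes.values() for w in n.out_edges.values()]
    assert weights == [2, 2, 2]
    assert g.spell(1) == "ACGT"


def test_fuse_mismatch_creates_aligned_fork(scheme):
    """Mismatched column forks into aligned alternatives and rejoins after."""
    g = graph_from_sequence("ACGT", 0)
    _, path = align_to_graph(g, "AGGT", scheme)
    fuse_alignment(g, "AGGT", path, 1)
    assert len(g.nodes) == 5
    c = next(n for n in g.nodes.values() if n.base == "C")
    new_g = next(n for n in g.nodes.values() if n.base == "G" and n.aligned_ids)
    assert new_g.aligned_ids == {c.id}
    assert c.aligned_ids == {new_g.id}
    # fork at the mismatched column: both alternatives share pred and succ
    assert set(c.in_edges) == set(new_g.in_edges)
    assert set(c.out_edges) == set(new_g.out_edges)
    assert g.spell(1) == "AGGT"


def test_fuse_third_sequence_reuses_aligned_partner(scheme):
    g = graph_from_sequence("ACGT", 0)
    for k, s in enumerate(["AGGT", "AGGT"], start=1):
        _, path = align_to_graph(g, s, scheme)
        fuse_alignment(g, s, path, k)
    assert len(g.nodes) == 5  # second AGGT merges into the existing G node
    new_g = next(n for n in g.nodes.values() if n.base == "G" and n.aligned_ids)
    assert {s for s, _ in new_g.members} == {1, 2}


def test_fuse_round_trip_randomized(scheme):
    rng = np.random.default_rng(15)
    for t in range(25):
        seqs = dataset(4, int(rng.integers(20, 120)),
                       MutationModel(0.15, 0.06, 0.06, 0.7, seed=700 + t))
        g = graph_from_sequence(seqs[0], 0)
        for k, s in enumerate(seqs[1:], start=1):
            _, p = align_to_graph(g, s, scheme)
            fuse_alignment(g, s, p, k)
            g.topological_order()  # acyclicity preserved
        for k, s in enumerate(seqs):
            assert g.spell(k) == s


# --- MSA rows --------------------------------------------------------------------


def test_msa_identical_sequences(scheme):
    rows, _ = msa(["ACGT", "ACGT", "ACGT"], scheme)
    assert rows == ["ACGT", "ACGT", "ACGT"]


def test_msa_two_sequences_equal_length_rows(scheme):
    rows, _ = msa(["ACGT", "AGGT"], scheme)
    assert len(rows[0]) == len(rows[1])
    assert rows[0].replace("-", "") == "ACGT"
    assert rows[1].replace("-", "") == "AGGT"


def test_msa_rows_single_sequence(scheme):
    g = graph_from_sequence("ACGTA", 0)
    assert msa_rows_from_graph(g) == ["ACGTA"]


def test_msa_rows_figure_topology_shares_column(scheme):
    g = graph_from_sequence("ACGT", 0)
    _, path = align_to_graph(g, "AGGT", scheme)
    fuse_alignment(g, "AGGT", path, 1)
    rows = msa_rows_from_graph(g)
    assert rows == ["ACGT", "AGGT"]  # 4 columns, C/G stacked at column 2


def test_msa_round_trip_property(scheme):
    rng = np.random.default_rng(16)
    for t in range(10):
        n = 5 if t % 2 else 10
        seqs = dataset(n, int(rng.integers(50, 400)), MutationModel(seed=900 + t))
        rows, _ = msa(seqs, scheme)
        assert len({len(r) for r in rows}) == 1
        for k, s in enumerate(seqs):
            assert rows[k].replace("-", "") == s


def test_msa_requires_nonempty_input(scheme):
    with pytest.raises(InputError):
        msa([], scheme)
    with pytest.raises(InputError):
        msa(["ACGT", ""], scheme)
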