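"""Ladder scheduler: partitioning, boundary stitching, wave safety, determinism."""

import threading
import time

import numpy as np
import pytest

from trapalign.blocks import (
    BlockFailure,
    execute_ladder,
    partition_matrix,
    stitch_boundaries,
    synthetic_left_packet,
    synthetic_top_packet,
)
from trapalign.engine import EngineParams, align_pairwise
from trapalign.errors import ConfigError
from trapalign.oracle import global_affine_dp, global_affine_score
from trapalign.scoring import NEG_INF
from trapalign.simulate import mutated_pair


def wave_sizes(plan):
    return [len(w) for w in plan.waves]


def test_partition_square_census():
    plan = partition_matrix(64, 64, 16)
    assert plan.n_blocks == 16
    assert wave_sizes(plan) == [1, 2, 3, 4, 3, 2, 1]


def test_partition_single_block():
    plan = partition_matrix(10, 10, 16)
    assert plan.n_blocks == 1
    assert wave_sizes(plan) == [1]
    task = plan.waves[0][0]
    assert task.shape == (10, 10)


def test_partition_ragged_edges():
    plan = partition_matrix(100, 50, 16)
    assert (plan.n_block_rows, plan.n_block_cols) == (7, 4)
    assert len(plan.waves) == 10
    last = plan.waves[-1][0]
    assert (last.row_start, last.row_stop) == (97, 101)
    assert (last.col_start, last.col_stop) == (49, 51)
    # work conservation: block cells tile the matrix exactly once
    total = sum(t.shape[0] * t.shape[1] for w in plan.waves for t in w)
    assert total == 100 * 50


def test_wave_membership_is_antidiagonal():
    plan = partition_matrix(80, 48, 16)
    for w, wave in enumerate(plan.waves):
        assert all(t.bi + t.bj == w for t in wave)
        assert len(wave) == sum(
            1 for bi in range(plan.n_block_rows) for bj in range(plan.n_block_cols)
            if bi + bj == w
        )


def test_synthetic_boundaries_are_gap_series(scheme):
    top = synthetic_top_packet(1, 6, scheme)
    o, e = scheme.gap_open, scheme.gap_extend
    assert top.anchor == 0
    assert list(top.diffs) == [o + e, e, e, e, e, e]
    assert all(v == NEG_INF for v in top.gap_rel)
    left = synthetic_left_packet(5, 4, scheme)
    assert left.anchor == o + 4 * e
    assert list(left.diffs) == [e] * 4
    # anchored reconstruction reproduces the oracle boundary
    dp = global_affine_dp("A" * 12, "A" * 12, scheme)
    assert list(top.absolute()) == list(dp.M[0, 1:7])
    assert list(left.absolute()) == list(dp.M[5:9, 0])


def test_stitch_rejects_mismatched_packets(scheme):
    plan = partition_matrix(8, 8, 8)
    task = plan.waves[0][0]
    top = synthetic_top_packet(1, 8, scheme)
    left = synthetic_left_packet(1, 4, scheme)  # wrong height
    from trapalign.errors import InternalError

    with pytest.raises(InternalError):
        stitch_boundaries(left, top, task)


def test_block_rims_match_oracle(scheme):
    """Anchored reconstruction on every interior block rim equals the oracle."""
    ref, qry = mutated_pair(70, "high", 3)
    dp = global_affine_dp(ref, qry, scheme)
    params = EngineParams(lanes=4, stripes=4)
    # capture packets by re-running the ladder with an instrumented block_fn
    from trapalign import _kernels
    from trapalign.scoring import encode

    rc, qc = encode(ref), encode(qry)
    sub = scheme.substitution_matrix()
    plan = partition_matrix(len(ref), len(qry), params.L)

    def block_fn(task, top, left):
        anchor, dH_top, erel_top, dV_left, frel_left = stitch_boundaries(left, top, task)
        # the incoming top rim must equal the oracle's M row above the block
        i0, j0 = task.row_start - 1, task.col_start - 1
        assert anchor == dp.M[i0, j0]
        assert list(top.absolute()) == list(dp.M[i0, task.col_start : task.col_stop])
        assert list(left.absolute()) == list(dp.M[task.row_start : task.row_stop, j0])
        h, w = task.shape
        outs = [np.empty(w, np.int64), np.empty(w, np.int64),
                np.empty(h, np.int64), np.empty(h, np.int64)]
        ov = np.empty(2, np.int64)
        _kernels.block_update(
            rc[task.row_start - 1 : task.row_stop - 1],
            qc[task.col_start - 1 : task.col_stop - 1],
            sub, scheme.gap_open, scheme.gap_extend, params.lanes,
            params.effective_stripes,
            np.ascontiguousarray(dH_top), np.ascontiguousarray(erel_top),
            np.ascontiguousarray(dV_left), np.ascontiguousarray(frel_left),
            *outs, np.zeros((1, 1), np.uint8), False, 0, 0, False, ov,
        )
        from trapalign.blocks import BoundaryPacket

        bottom = BoundaryPacket(anchor + int(np.sum(dV_left)), outs[0], outs[1])
        right = BoundaryPacket(anchor + int(np.sum(dH_top)), outs[2], outs[3])
        return bottom, right

    final = execute_ladder(plan, 1, block_fn, scheme)
    assert final.absolute()[-1] == dp.score


@pytest.mark.parametrize("threads", [1, 2, 4, 8])
def test_ladder_determinism_across_workers(threads, scheme):
    ref, qry = mutated_pair(150, "high", 17)
    base = align_pairwise(ref, qry, scheme,
                          EngineParams(lanes=8, stripes=2, threads=1, traceback=True))
    got = align_pairwise(ref, qry, scheme,
                         EngineParams(lanes=8, stripes=2, threads=threads, traceback=True))
    assert (got.score, got.cigar) == (base.score, base.cigar)


@pytest.mark.parametrize("stripes", [1, 2, 4, 8])
def test_block_size_invariance(stripes, scheme):
    ref, qry = mutated_pair(200, "low", 23)
    expected = global_affine_score(ref, qry, scheme)
    got = align_pairwise(ref, qry, scheme, EngineParams(lanes=8, stripes=stripes))
    assert got.score == expected


def test_single_block_plan_equals_direct_call(scheme):
    ref, qry = mutated_pair(20, "low", 4)
    small = align_pairwise(ref, qry, scheme, EngineParams(lanes=8, stripes=4))
    big = align_pairwise(ref, qry, scheme, EngineParams(lanes=8, stripes=8, block_side=64))
    assert small.score == big.score == global_affine_score(ref, qry, scheme)


def test_wave_barrier_no_overlap(scheme):
    """Instrumented run: no wave-w+1 block starts before the last wave-w finish."""
    ref, qry = mutated_pair(120, "low", 8)
    plan = partition_matrix(len(ref), len(qry), 16)
    stamps = []
    lock = threading.Lock()

    from trapalign.blocks import BoundaryPacket

    def block_fn(task, top, left):
        t_start = time.monotonic()
        time.sleep(0.001)
        t_stop = time.monotonic()
        with lock:
            stamps.append((task.wave, t_start, t_stop))
        h, w = task.shape
        return (BoundaryPacket(0, np.zeros(w, np.int64), np.zeros(w, np.int64)),
                BoundaryPacket(0, np.zeros(h, np.int64), np.zeros(h, np.int64)))

    execute_ladder(plan, 4, block_fn, scheme)
    by_wave = {}
    for w, t0, t1 in stamps:
        lo, hi = by_wave.get(w, (t0, t1))
        by_wave[w] = (min(lo, t0), max(hi, t1))
    waves = sorted(by_wave)
    for a, b in zip(waves, waves[1:]):
        assert by_wave[b][0] >= by_wave[a][1]


def test_block_failure_carries_coordinates(scheme):
    plan = partition_matrix(40, 40, 16)

    def block_fn(task, top, left):
        raise ValueError("boom")

    with pytest.raises(BlockFailure, match=r"block \(0,0\)"):
        execute_ladder(plan, 2, block_fn, scheme)


def test_worker_count_validated(scheme):
    plan = partition_matrix(4, 4, 4)
    with pytest.raises(ConfigError):
        execute_ladder(plan, 0, lambda *a: None, scheme)
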