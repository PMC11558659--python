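"""Shared fixtures and independent mini-oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from trapalign.scoring import ScoringScheme

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


def enumerate_global_alignments(n: int, m: int):
    """Every op string over {M, I, D} consuming n reference and m query bases.

    Exhaustive enumeration; only usable for tiny n, m.
    """
    if n == 0 and m == 0:
        yield ""
        return
    if n > 0 and m > 0:
        for rest in enumerate_global_alignments(n - 1, m - 1):
            yield "M" + rest
    if n > 0:
        for rest in enumerate_global_alignments(n - 1, m):
            yield "D" + rest
    if m > 0:
        for rest in enumerate_global_alignments(n, m - 1):
            yield "I" + rest


def score_ops(ops: str, ref: str, qry: str, scheme: ScoringScheme) -> int:
    """Affine-gap score of one explicit op string (gap runs scored o + k*e)."""
    score = 0
    i = j = 0
    prev = None
    for op in ops:
        if op == "M":
            if ref[i].upper() == qry[j].upper() and ref[i].upper() != "N":
                score += scheme.match
            else:
                score += scheme.mismatch
            i += 1
            j += 1
        else:
            if op != prev:
                score += scheme.gap_open
            score += scheme.gap_extend
            if op == "D":
                i += 1
            else:
                j += 1
        prev = op
    return score


@lru_cache(maxsize=None)
def brute_force_score_cached(ref: str, qry: str, match, mismatch, gap_open, gap_ext) -> int:
    scheme = ScoringScheme(match, mismatch, gap_open, gap_ext)
    return max(
        score_ops(ops, ref, qry, scheme)
        for ops in enumerate_global_alignments(len(ref), len(qry))
    )


def brute_force_score(ref: str, qry: str, scheme: ScoringScheme) -> int:
    """Optimal global score by exhaustive enumeration (tiny inputs only)."""
    return brute_force_score_cached(
        ref, qry, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
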