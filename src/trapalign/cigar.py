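"""CIGAR helpers: run-length encoding, re-scoring, conservation checks.

Operators follow SAM semantics restricted to global alignment: ``M`` aligns a
reference base to a query base (match or mismatch), ``I`` consumes query
only, ``D`` consumes reference only.
"""

from __future__ import annotations

import re

from .errors import InputError
from .scoring import ScoringScheme, gap_cost, substitution_score

_CIGAR_RE = re.compile(r"(\d+)([MID])")


def cigar_to_string(ops: list[str]) -> str:
    """Run-length encode a list of single-op characters."""
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) runs, validating the syntax."""
    runs = []
    pos = 0
    for mo in _CIGAR_RE.finditer(cigar):
        if mo.start() != pos:
            raise InputError(f"malformed CIGAR at offset {pos}: {cigar!r}")
        runs.append((int(mo.group(1)), mo.group(2)))
        pos = mo.end()
    if pos != len(cigar):
        raise InputError(f"malformed CIGAR at offset {pos}: {cigar!r}")
    return runs


def cigar_lengths(cigar: str) -> tuple[int, int]:
    """(reference length consumed, query length consumed) = (M+D, M+I)."""
    ref = qry = 0
    for k, op in parse_cigar(cigar):
        if op in "MD":
            ref += k
        if op in "MI":
            qry += k
    return ref, qry


def rescore_cigar(
    cigar: str, reference: str, query: str, scheme: ScoringScheme | None = None
) -> int:
    """Score the alignment a CIGAR describes; each I/D run is one affine gap."""
    scheme = scheme or ScoringScheme()
    rl, ql = cigar_lengths(cigar)
    if rl != len(reference) or ql != len(query):
        raise InputError(
            f"CIGAR covers {rl} reference / {ql} query bases but sequences "
            f"are {len(reference)} / {len(query)}"
        )
    score = 0
    i = j = 0
    for k, op in parse_cigar(cigar):
        if op == "M":
            for _ in range(k):
                score += substitution_score(reference[i], query[j], scheme)
                i += 1
                j += 1
        elif op == "D":
            score += gap_cost(k, scheme)
            i += k
        else:  # I
            score += gap_cost(k, scheme)
            j += k
    return score
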