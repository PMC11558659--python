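"""Affine scoring scheme shared by every alignment engine.

The model is the classic affine gap penalty: a gap of length ``k`` costs
``gap_open + k * gap_extend`` (the opening surcharge is charged once, every
gap column including the first one is charged the extension). Substitutions
are scored by a match/mismatch pair over the DNA alphabet ``{A, C, G, T, N}``;
``N`` is treated as matching nothing, including another ``N``.

All scores are exact integers; no engine in this package ever touches
floating point inside a dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

#: alphabet order used for integer encoding
ALPHABET = "ACGTN"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE.update({c.lower(): i for i, c in enumerate(ALPHABET)})

#: -infinity sentinel for int64 dynamic programs.  Far below any reachable
#: score, but adding gap penalties repeatedly can never wrap an int64.
NEG_INF = -(1 << 40)


def is_neg_inf(x: int) -> bool:
    """True for any value in the sentinel band (sentinel plus bounded arithmetic)."""
    return x < NEG_INF // 2


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap parameters.

    Defaults are the benchmark settings used throughout this package:
    match 2, mismatch -3, gap open -4, gap extend -2, so a gap of length k
    costs ``-4 - 2k``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -4
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise InputError(
                f"match score ({self.match}) must exceed mismatch ({self.mismatch})"
            )
        if self.gap_extend >= 0:
            raise InputError(f"gap_extend must be negative, got {self.gap_extend}")
        if self.gap_open > 0:
            raise InputError(f"gap_open must be non-positive, got {self.gap_open}")

    # -- elementary costs ---------------------------------------------------

    def substitution_matrix(self) -> np.ndarray:
        """5x5 int64 matrix over the encoded alphabet; N mismatches everything."""
        m = np.full((5, 5), self.mismatch, dtype=np.int64)
        for i in range(4):
            m[i, i] = self.match
        # N vs anything (incl. N) is a mismatch
        return m


def substitution_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Score of aligning base ``a`` against base ``b`` (case-insensitive)."""
    scheme = scheme or ScoringScheme()
    for pos, c in enumerate((a, b)):
        if c not in _CODE:
            raise InputError(f"symbol {c!r} at argument {pos + 1} is not in {ALPHABET}")
    au, bu = a.upper(), b.upper()
    if au == bu and au != "N":
        return scheme.match
    return scheme.mismatch


def gap_cost(k: int, scheme: ScoringScheme | None = None) -> int:
    """Score of a single gap of length ``k``: 0 if empty, else open + k*extend."""
    scheme = scheme or ScoringScheme()
    if k < 0:
        raise InputError(f"gap length must be >= 0, got {k}")
    if k == 0:
        return 0
    return scheme.gap_open + k * scheme.gap_extend


_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i


def encode(seq: str, name: str = "sequence") -> np.ndarray:
    """Encode a nucleotide string as uint8 codes, validating the alphabet.

    Raises :class:`InputError` naming the offending symbol and its 0-based
    position.
    """
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError:
        raw = None
    if raw is None:
        bad = next(i for i, c in enumerate(seq) if ord(c) > 127)
        raise InputError(f"{name}: symbol {seq[bad]!r} at position {bad} is not in {ALPHABET}")
    out = _LUT[raw]
    if (out == 255).any():
        bad = int(np.argmax(out == 255))
        raise InputError(f"{name}: symbol {seq[bad]!r} at position {bad} is not in {ALPHABET}")
    return out


def validate(seq: str, name: str = "sequence") -> str:
    """Validate and uppercase a sequence string."""
    encode(seq, name)
    return seq.upper()
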