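"""Result containers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .engine import EngineParams
    from .scoring import ScoringScheme


@dataclass
class AlignmentResult:
    """Outcome of one pairwise alignment or one MSA.

    ``cigar`` is present only when traceback was requested; re-scoring it
    against the sequences reproduces ``score`` exactly.  ``msa_rows`` is the
    list of equal-length gapped rows for an MSA result.
    """

    score: int
    cigar: Optional[str]
    query_id: str = "query"
    reference_id: str = "reference"
    msa_rows: Optional[list[str]] = None
    scheme: Optional["ScoringScheme"] = None
    params: Optional["EngineParams"] = None
    elapsed: Optional[float] = None  # informational only, never part of the contract
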