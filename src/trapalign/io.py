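"""FASTA input/output and result writers."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .errors import InputError, StateError
from .results import AlignmentResult
from .scoring import _CODE


@dataclass(frozen=True)
class FastaRecord:
    """One validated, uppercased FASTA record."""

    id: str
    description: str
    sequence: str


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _locate_bad_symbol(path: str | Path, record_id: str, symbol: str) -> int | None:
    """Best-effort line number of an illegal sequence character."""
    in_record = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and symbol in line:
                return lineno
    return None


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[FastaRecord]:
    """Read a (possibly gzipped) FASTA file, validating the alphabet.

    Records keep input order; multi-line sequences are joined; CRLF endings
    are tolerated; sequences are uppercased.  Malformed headers, empty files
    and illegal characters raise :class:`InputError` with a line number where
    one can be determined.  ``allow_gaps`` additionally accepts ``-`` (for
    re-reading aligned FASTA).
    """
    records: list[FastaRecord] = []
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            raise InputError(f"{path}: empty file")
        if first != ">":
            raise InputError(f"{path}: line 1: expected a FASTA header starting with '>'")
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise InputError(f"{path}: record {len(records) + 1} has an empty id")
            seq = str(rec.seq).upper()
            for i, c in enumerate(seq):
                if c == "-" and allow_gaps:
                    continue
                if c not in _CODE:
                    lineno = _locate_bad_symbol(path, rec.id, c)
                    where = f"line {lineno}" if lineno else f"record {rec.id!r} position {i}"
                    raise InputError(f"{path}: {where}: illegal character {c!r}")
            records.append(FastaRecord(rec.id, rec.description, seq))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")


def write_alignment(
    result: AlignmentResult | list[AlignmentResult],
    fmt: str,
    path: str | Path | None = None,
    stream: TextIO | None = None,
) -> str:
    """Serialize results as ``tsv``, ``cigar`` or ``fasta-msa``.

    tsv: one line per pair (query id, reference id, score, cigar or '.').
    cigar: the bare CIGAR string(s), one per line.
    fasta-msa: equal-length gapped records of an MSA result.
    Output is byte-stable across runs.  Returns the serialized text (and
    writes it to ``path`` or ``stream`` when given).
    """
    results = result if isinstance(result, list) else [result]
    lines: list[str] = []
    if fmt == "tsv":
        for r in results:
            lines.append(f"{r.query_id}\t{r.reference_id}\t{r.score}\t{r.cigar or '.'}")
    elif fmt == "cigar":
        for r in results:
            if r.cigar is None:
                raise StateError("cigar output requested but no traceback was kept")
            lines.append(r.cigar)
    elif fmt == "fasta-msa":
        for r in results:
            if r.msa_rows is None:
                raise StateError("fasta-msa output requested for a pairwise-only result")
            ids = r.query_id if isinstance(r.query_id, list) else [
                f"seq{k}" for k in range(len(r.msa_rows))
            ]
            for rid, row in zip(ids, r.msa_rows):
                lines.append(f">{rid}")
                lines.append(row)
    else:
        raise InputError(f"unknown output format {fmt!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    if stream is not None:
        stream.write(text)
    return text
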