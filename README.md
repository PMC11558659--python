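# trapalign

Exact global sequence alignment for long reads: difference-recurrence
dynamic programming evaluated in striped lane-vectors with an Active-F
correction, tiled into anti-diagonal ("ladder") blocks scheduled across
threads, plus partial-order-graph multiple sequence alignment built on the
same machinery.  Every optimized engine is verified bit-for-bit against a
plain Needleman–Wunsch–Gotoh oracle.

It is written for people who need *optimal* (not heuristic) global
alignments of DNA sequences — method developers, benchmark authors, and
anyone validating a faster aligner — and for studying the algorithms
themselves: every layer (difference cells, stripe layout, Active-F phases,
boundary packets, POA fusion) is exposed as a tested, documented Python API.

## The model

Alignment is scored with the affine gap model: match/mismatch scores and a
gap of length *k* costing *o + k·e* (defaults: match 2, mismatch −3,
*o* = −4, *e* = −2), via the three-matrix recurrence

```
E(i,j) = max( E(i−1,j) + e,  M(i−1,j) + o + e )
F(i,j) = max( F(i,j−1) + e,  M(i,j−1) + o + e )
M(i,j) = max( E(i,j), F(i,j), M(i−1,j−1) + q(i,j) )
```

The optimized engine stores per-cell *differences* (ΔH, ΔV, and the diagonal
difference S = max(E, q, F) with ΔV = S − ΔH_above, ΔH = S − ΔV_left)
instead of absolute scores, processes each row in striped order so a vector
of S lanes advances S non-adjacent cells at once, repairs the horizontal
dependency with a single update-and-rerun pass (Active-F), and tiles the
matrix into L×L blocks whose anti-diagonal waves are independent and
thread-parallel.  Multiple alignment generalizes the same recurrence to a
partial-order graph: a cell draws from every predecessor node, and aligned
sequences are fused back into the graph.  Details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a 60-base sequence and one long-read-style mutated copy, then align
them:

```sh
$ trapalign simulate -n 2 -l 60 --seed 11 -o pair.fa
$ trapalign psa pair.fa --traceback
seq1	seq0	96	10M1D13M1I36M
```

The query `seq1` aligns to the reference `seq0` with optimal global score
96: of the 59 aligned columns, 57 match (+114) and 2 mismatch (−6), and the
two single-base gaps cost −6 each (open −4 + extend −2), so
114 − 6 − 12 = 96.  The CIGAR reads: 10 aligned columns, one reference-only
base (`D`), 13 aligned columns, one query-only base (`I`), 36 aligned
columns.
Re-scoring the CIGAR against the sequences reproduces 96 exactly — that
identity is asserted for every traced alignment in the test suite.

The same file through the MSA engine:

```sh
$ trapalign msa pair.fa
>seq0
GTGTGGGAGGCCTATTGCGTTGTT-GTCCAGAAGGTAGAAAGACTGACCAAGTGTCCAGCA
>seq1
GTCTGGGAGG-CAATTGCGTTGTTAGTCCAGAAGGTAGAAAGACTGACCAAGTGTCCAGCA
```

Equal-length gapped rows; removing the `-` characters reproduces each input
byte-for-byte.

The library API mirrors the CLI:

```python
import trapalign as ta

r = ta.align_pairwise("ACGT", "AGGT", params=ta.EngineParams(traceback=True))
r.score, r.cigar          # (3, '4M')
rows, graph = ta.msa(["ACGT", "AGGT", "ACGT"])
rows                      # ['ACGT', 'AGGT', 'ACGT']
```

Useful knobs: `--lanes` (lane-vector width S), `-b/--stripes` (stripe count
D; the block side is L = S·D), `-t/--threads` (ladder workers), and
`--traceback` (CIGARs cost one byte per DP cell).  Results are bit-identical
across all of them.

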