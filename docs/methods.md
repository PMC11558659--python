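# Methods

## Model

All engines compute **global** pairwise or graph alignment under the affine
gap model.  With match/mismatch scores and gap parameters *o* (opening
surcharge) and *e* (per-column extension), a gap of length *k* costs
*o + k·e*, and the classic three-matrix recurrence holds:

```
E(i,j) = max( E(i-1,j) + e,  M(i-1,j) + o + e )      # vertical gap (D)
F(i,j) = max( F(i,j-1) + e,  M(i,j-1) + o + e )      # horizontal gap (I)
M(i,j) = max( E(i,j), F(i,j), M(i-1,j-1) + q(i,j) )
```

with boundary `M(i,0) = o + i·e`, `M(0,j) = o + j·e`, `M(0,0) = 0`, and the
inapplicable gap matrix at −∞ on row/column 0.  Scores are exact integers
throughout; no dynamic program ever touches floating point.  Defaults are
match 2, mismatch −3, *o* = −4, *e* = −2.  The alphabet is `{A, C, G, T, N}`;
`N` scores as a mismatch against everything, including another `N` — the
conservative choice for an undefined ambiguity code.

`reference_oracle` (module `trapalign.oracle`) implements this recurrence
directly over dense matrices and is the package's ground truth: every
optimized engine is required to reproduce its scores bit-exactly, and in
traceback mode its canonical path.

## Difference recurrences

The optimized pairwise engine stores per-cell **differences** instead of
absolute scores: `S = M(i,j) − M(i−1,j−1)` (diagonal), `ΔH = M(i,j) −
M(i,j−1)`, `ΔV = M(i,j) − M(i−1,j)`, plus the gap scores in the same
diagonal-anchored difference form (`Ed`, `Fd`).  The closure identities

```
S  = max(Ed, q, Fd)        ΔV = S − ΔH_above        ΔH = S − ΔV_left
```

make the recurrence self-contained, and because every difference is bounded
by the scoring constants, narrow integer lanes suffice for storage.  The
per-cell form lives in `trapalign.stripes.psa_diff_cell` (pairwise) and
`trapalign.poa.msa_diff_cell` (the multi-predecessor generalization: the
horizontal difference is maximized directly over predecessors, and the
per-predecessor vertical differences and gap candidates then close the
recurrence; with a single predecessor it reduces exactly to the pairwise
cell, which is verified numerically).

The printed forms of these recurrences admit more than one consistent index
convention; this package fixes the convention "incoming gap candidates are
anchored at the predecessor's diagonal cell", under which all identities
close algebraically, and anchors correctness to bit-exact agreement with the
absolute-score oracle rather than to any particular typesetting.

## Striped rows and Active-F

Within a row of *L = S·D* cells (S lanes, D stripes), cell *p* is assigned to
stripe *p mod D* and lane *p div D*, so one lane-vector of S elements
advances S non-adjacent cells at once and only the horizontal chain
(`F`/`ΔV` flowing left to right) crosses lane boundaries.  The row update
runs in three phases:

1. **Initial loop** — stripes in order, the horizontal carry fed stripe to
   stripe.  Lane 0's run is chained from the true left boundary, so its
   cells are exact; other lanes start from a −∞ carry and see only paths
   confined to their own run.
2. **Update** — one sequential sweep over the final carry.  The corrected
   gap score entering lane *l* is `max(phase-1 carry of lane l−1, corrected
   carry of lane l−1 + D·e)`: a cell is *breached* exactly when the decayed
   cross-lane carry strictly exceeds the phase-1 value.  Strict inequality
   keeps tie-breaks aligned with the oracle's preference order.  The decay
   term is exact because a gap re-opened from a carry-raised score can never
   beat pure extension of the carry itself (*o* ≤ 0).
3. **Final loop** — the stripe loop reruns from the corrected carries; every
   cell now equals the plain sequential evaluation.

A fourth verification pass (`active_f_breaches`) re-derives the horizontal
chain sequentially and confirms zero remaining breaches; it is exercised in
the acceptance suite.  This one-update-then-rerun scheme contrasts with the
iterate-until-fixed "lazy" correction: the work per row is fixed at two
stripe sweeps plus one carry sweep, independent of gap structure.

Internally the row kernel telescopes the differences into a block-relative
integer frame (prefix sums of `ΔH` against the block's corner anchor) to
resolve the horizontal chain, then emits pure differences again.  The
"lanes" are fixed-length integer arrays combined with elementwise max/add —
a portable stand-in for hardware vector registers; S is an ordinary
parameter.  Kernels are compiled with numba and release the GIL.

## Ladder (trapezoidal) blocks

The DP matrix is partitioned into `ceil(n/L) × ceil(m/L)` tiles; edge tiles
shrink rather than padding the matrix (padding occurs only inside the stripe
layout of a short final segment, using dummy cells whose candidates are −∞
and can never enter an optimal path).  Tiles with equal `bi + bj` form an
anti-diagonal **wave**; waves run in order with a barrier between them, and
tiles within a wave are independent and dispatched to a thread pool
(`threads = 1` degenerates to a plain loop, the canonical reference
execution).  Neighbouring tiles exchange **boundary packets**: the rim
differences (`ΔH` along the bottom edge, `ΔV` along the right edge), the rim
gap states relative to each rim cell's own score (`E − M`, `F − M`), and an
absolute anchor at the tile's outer corner, so anchored prefix sums
reproduce the oracle's absolute scores along both edges (tested per block).
The gap-state fields are required to stitch affine gaps across tile
boundaries.  Per tile, working memory is two alternating full-width rows.

Determinism: each tile's output is a pure function of its input packets, so
scores and CIGARs are bit-identical across lane, stripe, worker-count and
block-side choices; the suite asserts this over the full parameter grid.

## Traceback

In traceback mode each cell stores a 4-bit code: two bits for the score
source (diagonal / vertical gap / horizontal gap, with the canonical
preference diagonal > vertical > horizontal) and one extension bit per gap
matrix (ties prefer extension).  The walk is state-aware — it stays inside a
gap matrix while the extension bit holds — so affine runs are traced
correctly, and it reproduces the oracle's traceback exactly.  The store
costs one byte per cell and is allocated only when requested; score-only
alignment keeps nothing but the rim packets.

## Partial-order MSA

Sequences are incorporated progressively in input order (no guide tree): the
first sequence becomes a linear chain graph; each later sequence is aligned
to the graph and fused.  Graph alignment processes node rows in a canonical
topological order (Kahn's algorithm, min-id tie-break, and *group-aware*:
all members of an aligned group are emitted consecutively, which keeps MSA
column assignment monotone along every member sequence).  A node's diagonal
and vertical candidates are maximized over all its predecessors — the
five-direction generalization of the pairwise recurrence, with a virtual
source before every head node and the alignment ending at the best sink with
terminal gaps charged — and the horizontal chain is resolved by the same
three-phase striped row update.  Rows span the full query width (the stripe
count grows with the query), so lane/stripe settings affect only the layout;
the thread count is ignored because successive node rows are data-dependent.
Graph rows are kept in anchored (prefix-summed) integer form, since the
fusion step needs a full traceback anyway.

Fusion follows the aligned path: equal-base matches merge into the existing
node (edge weights count traversals); mismatches merge into an aligned-group
partner with the same base when one exists, otherwise a new node joins the
group; insertions become new chain nodes; deletions leave the graph
untouched.  Acyclicity is re-verified after every fusion.  MSA rows emit one
column per aligned group in topological order.  Consensus calling is out of
scope; edge weights are maintained so it can be added later.

## Synthetic data

The generator emulates long-read-style divergence: i.i.d. uniform reference
bases; per-position substitutions (to a uniformly chosen different base) and
geometric-length insertions/deletions applied left-to-right on original
coordinates.  Presets: `none` (0/0/0), `low` (2%/1%/1%), `long-read`
(5%/2.5%/2.5%, geometric p = 0.7 — the default), `high` (15%/5%/5%).  All
draws come from a single seeded generator; datasets spawn per-sequence seeds
from one root seed.  The generator does **not** model chimeras, quality
values, homopolymer-specific error profiles, or non-uniform base
composition, so passing tests demonstrate algorithmic correctness (exact
oracle equivalence holds for *any* input) but say nothing about biological
interpretation of alignments of real reads.

## Numerical and design choices

- `delta_width="exact"` uses int64: differences are bounded by the scoring
  constants and block-relative values by block side × max score, so int64
  cannot overflow at any legal input size; this keeps oracle agreement
  bit-exact without big-integer cost.  `"int8"` emulates 8-bit lanes and
  raises `LaneOverflowError` naming the first offending cell rather than
  saturating — failing loudly is testable, silent saturation is not.
- The −∞ sentinel is −2⁴⁰, far below any reachable score yet with ~2²³ of
  headroom for repeated gap additions before leaving the sentinel band
  (values below −2³⁹ are treated as −∞).
- Tie-breaks, everywhere: diagonal > vertical > horizontal; within a gap
  matrix, extension > opening; among graph predecessors, lowest topological
  rank.  One canonical optimum makes results comparable across engines,
  layouts and worker counts.
- Degenerate inputs: empty sequences short-circuit to pure gap costs ("" vs
  "" scores 0 with an empty CIGAR); the dense oracle refuses sides beyond
  10⁵ and points to the striped engine.
- Problem sizes in the test suite (up to 1,000 random pairs of length ≤ 200,
  200 fused graphs of ≤ 5 sequences × ≤ 100 bases, 100 MSA datasets of
  5–10 × 100–2,000 bases, one 10,000 × 10,000 pairwise instance) were chosen
  so the whole suite exercises every engine at full fidelity while staying
  comfortable on a laptop-class machine.

## Known limitations

- Global alignment only: no local, semi-global, or banded modes, and no
  linear-space traceback (the direction store is O(n·m) bytes).
- The thread pool helps only when multiple CPU cores are available; on a
  single core the barrier scheduler adds a small switching overhead.
- MSA cost grows with graph size; highly divergent inputs inflate the graph
  and slow later iterations.
- No consensus sequence, no two-piece affine gaps, no protein matrices.
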