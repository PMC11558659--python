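"""Compiled inner loops (numba, nogil) for the striped engine and the oracle.

The striped row kernel works in a *row-relative* frame: every value is an
integer offset from the score at the block's upper-left outer corner, so the
horizontal chain can be resolved with plain max/add arithmetic while the
engine's externally visible state remains pure differences (dH rows, dV
columns, gap states relative to their own cell).  All kernels release the
GIL so the anti-diagonal block scheduler gets true thread parallelism.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: -infinity sentinel; mirrors trapalign.scoring.NEG_INF (kept literal here so
#: the kernels have no Python-level imports).
NEG = -(1 << 40)


@njit(cache=True, nogil=True)
def striped_row(B, hb, fb, o, e, S, D, H, Fp):  # pragma: no cover - compiled
    """Three-phase striped update of one row.

    ``B[p]`` is the best of the diagonal and vertical candidates for cell p
    (row-relative).  ``hb``/``fb`` are the row's left rim: score and
    horizontal-gap score of the cell left of p=0.  Cell p lives in stripe
    ``p % D``, lane ``p // D``; a lane therefore owns a contiguous run of D
    cells and the stripe loop advances every lane's run by one cell.

    Phase 1 (initial loop): stripes in order, horizontal carry fed stripe to
    stripe; lanes other than 0 start from a -inf carry, so only paths that
    stay inside one lane's run are seen.  Phase 2 (update): a single
    sequential sweep over the final carry decides, per lane, whether the
    horizontal score was breached by the neighbouring lane; the corrected
    entering gap for lane l is max(phase-1 carry of lane l-1, corrected
    carry of lane l-1 decayed by D extensions).  Phase 3 (final loop):
    rerun the stripe loop from the corrected carries; every cell is now the
    exact sequential value.

    Fills ``H`` (row scores) and ``Fp`` (horizontal-gap scores), both
    row-relative, length S*D (cells beyond the real row are padding and must
    carry B = -inf).
    """
    cF = np.empty(S, np.int64)
    cH = np.empty(S, np.int64)
    for l in range(S):
        cF[l] = NEG
        cH[l] = NEG
    cF[0] = fb
    cH[0] = hb
    # phase 1: initial loop
    for s in range(D):
        for l in range(S):
            p = l * D + s
            f = max(cF[l], cH[l] + o) + e
            h = max(B[p], f)
            Fp[p] = f
            H[p] = h
            cF[l] = f
            cH[l] = h
    # phase 2: update the carry (test per lane whether the horizontal score
    # has been breached)
    g = np.empty(S, np.int64)
    g[0] = max(fb, hb + o) + e
    De = D * e
    for l in range(1, S):
        p1 = max(cF[l - 1], cH[l - 1] + o) + e
        gl = g[l - 1] + De
        g[l] = gl if gl > p1 else p1
    # phase 3: final loop from the corrected carries
    cF[0] = fb
    cH[0] = hb
    for l in range(1, S):
        cF[l] = g[l] - e
        cH[l] = NEG
    for s in range(D):
        for l in range(S):
            p = l * D + s
            f = max(cF[l], cH[l] + o) + e
            h = max(B[p], f)
            Fp[p] = f
            H[p] = h
            cF[l] = f
            cH[l] = h


@njit(cache=True, nogil=True)
def row_breach_count(B, hb, fb, o, e, H, Fp, w):  # pragma: no cover - compiled
    """Verification pass: count cells whose horizontal term is still breached.

    A cell is breached when the exact sequential horizontal candidate strictly
    exceeds the stored value.  After phase 3 this must be zero for the first
    ``w`` (non-padding) cells.
    """
    count = 0
    ph = hb
    pf = fb
    for p in range(w):
        f = max(pf, ph + o) + e
        h = max(B[p], f)
        if f > Fp[p] or h > H[p]:
            count += 1
        ph = H[p]
        pf = Fp[p]
    return count


@njit(cache=True, nogil=True)
def block_update(
    ref_codes,
    qry_codes,
    submat,
    o,
    e,
    S,
    D,
    dH_top,
    Erel_top,
    dV_left,
    Frel_left,
    dH_bot,
    Erel_bot,
    dV_right,
    Frel_right,
    dirs,
    store_dirs,
    lane_min,
    lane_max,
    check_lanes,
    overflow_out,
):  # pragma: no cover - compiled
    """Compute one L x L (possibly ragged) block of the difference DP.

    Inputs are the boundary packets in difference form: ``dH_top``/``Erel_top``
    along the top edge (horizontal difference and vertical-gap state relative
    to the cell's own score), ``dV_left``/``Frel_left`` down the left edge.
    Outputs are the same quantities on the bottom and right edges.  Working
    memory is two alternating full-width rows (previous-row scores ``P`` and
    the current row ``H``), both relative to the block's corner anchor.

    When ``store_dirs`` is true, fills ``dirs`` with 4-bit traceback codes:
    bits 0-1 = source of the cell score (0 diagonal, 1 vertical gap, 2
    horizontal gap, preference diagonal > vertical > horizontal), bit 2 =
    vertical gap extends, bit 3 = horizontal gap extends (ties prefer
    extension).

    When ``check_lanes`` is true, verifies that every difference-form value
    (S, dH, dV, E, F) fits [lane_min, lane_max]; on violation writes the
    (row, col) block-local coordinates to ``overflow_out`` and returns early.
    """
    h = ref_codes.shape[0]
    w = qry_codes.shape[0]
    L = S * D
    P = np.empty(w + 1, np.int64)
    P[0] = 0
    for p in range(w):
        P[p + 1] = P[p] + dH_top[p]
    Erel = np.empty(w, np.int64)
    for p in range(w):
        Erel[p] = Erel_top[p]
    Ecand = np.empty(w, np.int64)
    B = np.empty(L, np.int64)
    H = np.empty(L, np.int64)
    Fp = np.empty(L, np.int64)
    for p in range(w, L):
        B[p] = NEG
    overflow_out[0] = -1
    overflow_out[1] = -1
    lm_prev = 0
    for r in range(h):
        lm = lm_prev + dV_left[r]
        rc = ref_codes[r]
        for p in range(w):
            ec = Erel[p]
            if ec < o:
                ec = o
            ec += e
            Ecand[p] = ec
            diag = P[p] + submat[rc, qry_codes[p]]
            vert = P[p + 1] + ec
            B[p] = diag if diag >= vert else vert
        fb = Frel_left[r] + lm
        striped_row(B, lm, fb, o, e, S, D, H, Fp)
        if store_dirs:
            for p in range(w):
                hp = H[p]
                code = 2
                if hp == P[p] + submat[rc, qry_codes[p]]:
                    code = 0
                elif hp == P[p + 1] + Ecand[p]:
                    code = 1
                if Erel[p] >= o:
                    code |= 4
                prev_f = fb if p == 0 else Fp[p - 1]
                prev_h = lm if p == 0 else H[p - 1]
                if prev_f >= prev_h + o:
                    code |= 8
                dirs[r, p] = code
        if check_lanes:
            for p in range(w):
                s_val = H[p] - P[p]
                dh = H[p] - (lm if p == 0 else H[p - 1])
                dv = H[p] - P[p + 1]
                ed = Ecand[p] + P[p + 1] - P[p]
                fd = Fp[p] - P[p]
                bad = False
                if s_val > NEG // 2 and (s_val < lane_min or s_val > lane_max):
                    bad = True
                if dh > NEG // 2 and (dh < lane_min or dh > lane_max):
                    bad = True
                if dv > NEG // 2 and (dv < lane_min or dv > lane_max):
                    bad = True
                if ed > NEG // 2 and (ed < lane_min or ed > lane_max):
                    bad = True
                if fd > NEG // 2 and (fd < lane_min or fd > lane_max):
                    bad = True
                if bad:
                    overflow_out[0] = r
                    overflow_out[1] = p
                    return
        for p in range(w):
            Erel[p] = Ecand[p] + P[p + 1] - H[p]
        dV_right[r] = H[w - 1] - P[w]
        Frel_right[r] = Fp[w - 1] - H[w - 1]
        P[0] = lm
        for p in range(w):
            P[p + 1] = H[p]
        lm_prev = lm
    for p in range(w):
        dH_bot[p] = P[p + 1] - P[p]
        Erel_bot[p] = Erel[p]


@njit(cache=True, nogil=True)
def gotoh_fill(ref_codes, qry_codes, submat, o, e, M, E, F):  # pragma: no cover
    """Plain absolute-score Needleman-Wunsch-Gotoh fill (the reference oracle).

    Global boundary: M[i][0] and M[0][j] are pure gap costs; E is undefined
    (-inf) on row 0, F undefined on column 0.
    """
    n = ref_codes.shape[0]
    m = qry_codes.shape[0]
    M[0, 0] = 0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for j in range(1, m + 1):
        F[0, j] = o + j * e
        M[0, j] = F[0, j]
        E[0, j] = NEG
    for i in range(1, n + 1):
        E[i, 0] = o + i * e
        M[i, 0] = E[i, 0]
        F[i, 0] = NEG
        for j in range(1, m + 1):
            ev = max(E[i - 1, j] + e, M[i - 1, j] + o + e)
            fv = max(F[i, j - 1] + e, M[i, j - 1] + o + e)
            mv = M[i - 1, j - 1] + submat[ref_codes[i - 1], qry_codes[j - 1]]
            if ev > mv:
                mv = ev
            if fv > mv:
                mv = fv
            E[i, j] = ev
            F[i, j] = fv
            M[i, j] = mv
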