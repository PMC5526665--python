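"""Scalar dynamic-programming kernels for pairwise nucleotide alignment.

Two kernels:

* :func:`extend_kernel` — anchored, banded, affine-gap extension with X-drop
  termination, used by the seed-and-extend aligner.
* :func:`sw_kernel` — full affine-gap Smith–Waterman over the whole DP matrix,
  quadratic in time; kept as an exhaustive reference for validating the
  seeded aligner on small inputs.

Both carry companion match/column counts along the optimal path so percent
identity can be reported without a traceback.  Sequences are uint8-encoded
(A=0, C=1, G=2, T=3, N=4); code 4 never matches anything, including itself.

Kernels are compiled with numba when importable and fall back to pure Python
otherwise (slow but correct).
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(func):
            return func

        return wrap


NEG = -(10**9)


@njit(cache=False)
def extend_kernel(q, s, match, mismatch, gap_open, gap_extend, band, xdrop):
    """Extend an alignment anchored at (0, 0) over ``q`` vs ``s``.

    Returns ``(score, q_extent, s_extent, n_matches, n_columns)`` for the
    best-scoring cell reachable from the anchor.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  Rows whose best score falls more
    than ``xdrop`` below the running optimum terminate the extension.
    """
    nq = q.shape[0]
    ns = s.shape[0]
    W = 2 * band + 1
    neg = NEG

    prevH = np.full(W, neg, np.int64)
    prevHm = np.zeros(W, np.int64)
    prevHc = np.zeros(W, np.int64)
    prevF = np.full(W, neg, np.int64)
    prevFm = np.zeros(W, np.int64)
    prevFc = np.zeros(W, np.int64)

    curH = np.full(W, neg, np.int64)
    curHm = np.zeros(W, np.int64)
    curHc = np.zeros(W, np.int64)
    curF = np.full(W, neg, np.int64)
    curFm = np.zeros(W, np.int64)
    curFc = np.zeros(W, np.int64)
    curE = np.full(W, neg, np.int64)
    curEm = np.zeros(W, np.int64)
    curEc = np.zeros(W, np.int64)

    # Row 0: anchor plus leading gaps in the query (consuming subject).
    for k in range(band, W):
        j = k - band
        if j > ns:
            break
        if j == 0:
            prevH[k] = 0
        else:
            prevH[k] = gap_open + (j - 1) * gap_extend
            prevHc[k] = j

    best_score = 0
    best_i = 0
    best_j = 0
    best_m = 0
    best_c = 0

    for i in range(1, nq + 1):
        rowbest = neg
        for k in range(W):
            curH[k] = neg
            curF[k] = neg
            curE[k] = neg
        for k in range(W):
            j = i + k - band
            if j < 0 or j > ns:
                continue
            if j == 0:
                h = gap_open + (i - 1) * gap_extend
                curH[k] = h
                curHm[k] = 0
                curHc[k] = i
                curF[k] = h
                curFm[k] = 0
                curFc[k] = i
                if h > rowbest:
                    rowbest = h
                continue
            # Diagonal from (i-1, j-1): same band offset in the previous row.
            qc = q[i - 1]
            sc = s[j - 1]
            is_match = qc == sc and qc < 4
            diag = neg
            dm = 0
            dc = 0
            if prevH[k] > neg // 2:
                diag = prevH[k] + (match if is_match else mismatch)
                dm = prevHm[k] + (1 if is_match else 0)
                dc = prevHc[k] + 1
            # F: gap in subject, from (i-1, j) = previous row, offset k+1.
            f = neg
            fm = 0
            fc = 0
            if k + 1 < W:
                fo = neg
                fe = neg
                if prevH[k + 1] > neg // 2:
                    fo = prevH[k + 1] + gap_open
                if prevF[k + 1] > neg // 2:
                    fe = prevF[k + 1] + gap_extend
                if fo >= fe:
                    if fo > neg // 2:
                        f = fo
                        fm = prevHm[k + 1]
                        fc = prevHc[k + 1] + 1
                else:
                    f = fe
                    fm = prevFm[k + 1]
                    fc = prevFc[k + 1] + 1
            curF[k] = f
            curFm[k] = fm
            curFc[k] = fc
            # E: gap in query, from (i, j-1) = current row, offset k-1.
            e = neg
            em = 0
            ec = 0
            if k - 1 >= 0:
                eo = neg
                ee = neg
                if curH[k - 1] > neg // 2:
                    eo = curH[k - 1] + gap_open
                if curE[k - 1] > neg // 2:
                    ee = curE[k - 1] + gap_extend
                if eo >= ee:
                    if eo > neg // 2:
                        e = eo
                        em = curHm[k - 1]
                        ec = curHc[k - 1] + 1
                else:
                    e = ee
                    em = curEm[k - 1]
                    ec = curEc[k - 1] + 1
            curE[k] = e
            curEm[k] = em
            curEc[k] = ec
            # H = best of the three states; ties prefer diagonal, then E.
            h = diag
            hm = dm
            hc = dc
            if e > h:
                h = e
                hm = em
                hc = ec
            if f > h:
                h = f
                hm = fm
                hc = fc
            if h <= neg // 2:
                continue
            curH[k] = h
            curHm[k] = hm
            curHc[k] = hc
            if h > rowbest:
                rowbest = h
            if h > best_score:
                best_score = h
                best_i = i
                best_j = j
                best_m = hm
                best_c = hc
        if rowbest < best_score - xdrop:
            break
        for k in range(W):
            prevH[k] = curH[k]
            prevHm[k] = curHm[k]
            prevHc[k] = curHc[k]
            prevF[k] = curF[k]
            prevFm[k] = curFm[k]
            prevFc[k] = curFc[k]

    return best_score, best_i, best_j, best_m, best_c


@njit(cache=False)
def sw_kernel(q, s, match, mismatch, gap_open, gap_extend):
    """Full Smith–Waterman with affine gaps.

    Returns ``(score, end_i, end_j, n_matches, n_columns)`` of the best local
    alignment.  Tie preference is diagonal > gap-in-query > gap-in-subject >
    restart, matching :func:`extend_kernel`.
    """
    nq = q.shape[0]
    ns = s.shape[0]
    neg = NEG

    prevH = np.zeros(ns + 1, np.int64)
    prevHm = np.zeros(ns + 1, np.int64)
    prevHc = np.zeros(ns + 1, np.int64)
    prevF = np.full(ns + 1, neg, np.int64)
    prevFm = np.zeros(ns + 1, np.int64)
    prevFc = np.zeros(ns + 1, np.int64)

    curH = np.zeros(ns + 1, np.int64)
    curHm = np.zeros(ns + 1, np.int64)
    curHc = np.zeros(ns + 1, np.int64)
    curF = np.full(ns + 1, neg, np.int64)
    curFm = np.zeros(ns + 1, np.int64)
    curFc = np.zeros(ns + 1, np.int64)

    best_score = 0
    best_i = 0
    best_j = 0
    best_m = 0
    best_c = 0

    for i in range(1, nq + 1):
        curH[0] = 0
        curHm[0] = 0
        curHc[0] = 0
        curF[0] = neg
        e = neg
        em = 0
        ec = 0
        qc = q[i - 1]
        for j in range(1, ns + 1):
            sc = s[j - 1]
            is_match = qc == sc and qc < 4
            diag = prevH[j - 1] + (match if is_match else mismatch)
            dm = prevHm[j - 1] + (1 if is_match else 0)
            dc = prevHc[j - 1] + 1
            # F: gap in subject (vertical).
            fo = prevH[j] + gap_open
            fe = prevF[j] + gap_extend if prevF[j] > neg // 2 else neg
            if fo >= fe:
                f = fo
                fm = prevHm[j]
                fc = prevHc[j] + 1
            else:
                f = fe
                fm = prevFm[j]
                fc = prevFc[j] + 1
            curF[j] = f
            curFm[j] = fm
            curFc[j] = fc
            # E: gap in query (horizontal).
            eo = curH[j - 1] + gap_open
            ee = e + gap_extend if e > neg // 2 else neg
            if eo >= ee:
                e = eo
                em = curHm[j - 1]
                ec = curHc[j - 1] + 1
            else:
                e = ee
                ec = ec + 1
            h = diag
            hm = dm
            hc = dc
            if e > h:
                h = e
                hm = em
                hc = ec
            if f > h:
                h = f
                hm = fm
                hc = fc
            # restart at <= 0: of co-optimal alignments prefer the shortest,
            # matching the extension kernel's strict-improvement rule
            if h <= 0:
                h = 0
                hm = 0
                hc = 0
            curH[j] = h
            curHm[j] = hm
            curHc[j] = hc
            if h > best_score:
                best_score = h
                best_i = i
                best_j = j
                best_m = hm
                best_c = hc
        for j in range(ns + 1):
            prevH[j] = curH[j]
            prevHm[j] = curHm[j]
            prevHc[j] = curHc[j]
            prevF[j] = curF[j]
            prevFm[j] = curFm[j]
            prevFc[j] = curFc[j]

    return best_score, best_i, best_j, best_m, best_c
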