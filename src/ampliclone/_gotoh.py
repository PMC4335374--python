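"""Banded semi-global Gotoh alignment kernel (numba).

Overlap-style semi-global alignment with affine gaps: end gaps on either
sequence's prefix/suffix are free, internal gaps cost open+extend for the
first base and extend per further base. The band is centred on the diagonal
estimated from a fast edit-distance prefilter; the caller widens the band and
retries whenever the optimal traceback touches the band boundary, so reported
scores are exact.

Score rows are rolled (only the previous row is kept); full uint8 pointer
matrices drive the traceback. Op codes emitted: 0 '=', 1 'X', 2 'I'
(insertion, consumes read), 3 'D' (deletion, consumes reference).
"""

from __future__ import annotations

import numba as nb
import numpy as np

NEG = np.int32(-(10**9))

OP_MATCH, OP_MISMATCH, OP_INS, OP_DEL = 0, 1, 2, 3


@nb.njit(cache=True, nogil=True)
def band_align(read, ref, r0, half_width, match, mismatch, gap_open, gap_extend):
    """Banded affine semi-global alignment.

    ``read``/``ref`` are uint8 arrays, ``r0`` the estimated reference start of
    the read (band centre diagonal), ``half_width`` the band half width.
    A gap of length L costs gap_open + L*gap_extend.

    Returns (score, read_start, read_end, ref_start, ref_end, ops, n_ops,
    touched): ops[:n_ops] are op codes along the alignment (read 5'->3') and
    ``touched`` flags a traceback step on the band boundary strictly inside
    the matrix — the signal to retry with a wider band.
    """
    n = read.size
    m = ref.size
    B = half_width
    W = 2 * B + 1
    neg = NEG

    # rolling score rows; j(i, k) = r0 + i + k - B
    Mp = np.empty(W + 2, np.int32)  # previous row, padded by one on each side
    Xp = np.empty(W + 2, np.int32)
    Yp = np.empty(W + 2, np.int32)
    Mc = np.empty(W + 2, np.int32)  # current row
    Xc = np.empty(W + 2, np.int32)
    Yc = np.empty(W + 2, np.int32)
    # full pointer matrices for traceback: 0=M, 1=X, 2=Y, 3=start
    pM = np.empty((n + 1, W), np.uint8)
    pX = np.empty((n + 1, W), np.uint8)
    pY = np.empty((n + 1, W), np.uint8)

    go_ge = gap_open + gap_extend

    # index shift: padded arrays use index k+1 for band offset k
    for k in range(W):
        j = r0 + k - B
        Mp[k + 1] = 0 if 0 <= j <= m else neg
        Xp[k + 1] = neg
        Yp[k + 1] = neg
        pM[0, k] = 3
    Mp[0] = Mp[W + 1] = neg
    Xp[0] = Xp[W + 1] = neg
    Yp[0] = Yp[W + 1] = neg
    Mc[0] = Mc[W + 1] = neg  # padded edges are never rewritten after this
    Xc[0] = Xc[W + 1] = neg
    Yc[0] = Yc[W + 1] = neg

    # best cell on the j == m column, tracked as rows stream by
    best = neg
    bi = 0
    bk = 0
    bmat = 0
    k0 = m - r0 + B  # k index of j == m at row 0
    if 0 <= k0 < W and Mp[k0 + 1] > best:
        best = Mp[k0 + 1]
        bi = 0
        bk = k0
        bmat = 0

    for i in range(1, n + 1):
        ci = r0 + i
        klo = 0 if ci - B >= 0 else B - ci
        khi = W if ci + B <= m else m - ci + B + 1
        if khi < klo:
            khi = klo
        Mc[klo] = neg  # sentinel at padded index klo (= band offset klo-1)
        Xc[klo] = neg
        Yc[klo] = neg
        if khi < W:
            Mc[khi + 1] = neg
            Xc[khi + 1] = neg
            Yc[khi + 1] = neg
        ri = read[i - 1]
        for k in range(klo, khi):
            kk = k + 1
            j = ci + k - B
            if j == 0:
                Mc[kk] = 0  # free read prefix: start at (i, 0)
                pM[i, k] = 3
                Xc[kk] = neg
                Yc[kk] = neg
                continue
            # M: diagonal predecessor (i-1, j-1) is the same k
            s = match if ri == ref[j - 1] else mismatch
            bm = Mp[kk]
            bp = np.uint8(0)
            if Xp[kk] > bm:
                bm = Xp[kk]
                bp = np.uint8(1)
            if Yp[kk] > bm:
                bm = Yp[kk]
                bp = np.uint8(2)
            if bm > neg:
                Mc[kk] = bm + s
                pM[i, k] = bp
            else:
                Mc[kk] = neg
                pM[i, k] = 3
            # X: from (i, j-1) = k-1, same row (open from M or Y, extend from X)
            vm = Mc[kk - 1]
            vy = Yc[kk - 1]
            bv = vm
            bq = np.uint8(0)
            if vy > bv:
                bv = vy
                bq = np.uint8(2)
            xv = neg
            xp = np.uint8(0)
            if bv > neg:
                xv = bv + go_ge
                xp = bq
            vx = Xc[kk - 1]
            if vx > neg and vx + gap_extend > xv:
                xv = vx + gap_extend
                xp = np.uint8(1)
            Xc[kk] = xv
            pX[i, k] = xp
            # Y: from (i-1, j) = k+1, previous row (open from M or X, extend from Y)
            vm = Mp[kk + 1]
            vx = Xp[kk + 1]
            bv = vm
            bq = np.uint8(0)
            if vx > bv:
                bv = vx
                bq = np.uint8(1)
            yv = neg
            yp = np.uint8(0)
            if bv > neg:
                yv = bv + go_ge
                yp = bq
            vy = Yp[kk + 1]
            if vy > neg and vy + gap_extend > yv:
                yv = vy + gap_extend
                yp = np.uint8(2)
            Yc[kk] = yv
            pY[i, k] = yp
        # track the j == m column (free read-suffix end) for rows i < n
        if i < n:
            km = m - ci + B
            if klo <= km < khi:
                if Mc[km + 1] > best:
                    best = Mc[km + 1]
                    bi = i
                    bk = km
                    bmat = 0
                if Xc[km + 1] > best:
                    best = Xc[km + 1]
                    bi = i
                    bk = km
                    bmat = 1
                if Yc[km + 1] > best:
                    best = Yc[km + 1]
                    bi = i
                    bk = km
                    bmat = 2
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp

    # last row (i = n, free ref-suffix end): after the final swap the row lives
    # in the "previous" arrays
    cn = r0 + n
    klo_n = 0 if cn - B >= 0 else B - cn
    khi_n = W if cn + B <= m else m - cn + B + 1
    for k in range(klo_n, khi_n):
        if Mp[k + 1] > best:
            best = Mp[k + 1]
            bi = n
            bk = k
            bmat = 0
        if Xp[k + 1] > best:
            best = Xp[k + 1]
            bi = n
            bk = k
            bmat = 1
        if Yp[k + 1] > best:
            best = Yp[k + 1]
            bi = n
            bk = k
            bmat = 2

    ops = np.empty(n + m + 2, np.uint8)
    n_ops = 0
    touched = False
    if best <= neg:
        return neg, 0, 0, 0, 0, ops, 0, True
    i, k, mat = bi, bk, bmat
    read_end = bi
    ref_end = r0 + bi + bk - B
    while True:
        j = r0 + i + k - B
        if (k == 0 or k == W - 1) and 0 < j < m and 0 < i < n:
            touched = True
        if mat == 0:
            if pM[i, k] == 3 or i == 0 or j == 0:
                break
            ops[n_ops] = OP_MATCH if read[i - 1] == ref[j - 1] else OP_MISMATCH
            n_ops += 1
            mat = pM[i, k]
            i -= 1  # diagonal: k unchanged
        elif mat == 1:
            ops[n_ops] = OP_DEL
            n_ops += 1
            mat = pX[i, k]
            k -= 1
        else:
            ops[n_ops] = OP_INS
            n_ops += 1
            mat = pY[i, k]
            i -= 1
            k += 1
    read_start = i
    ref_start = r0 + i + k - B
    # ops were collected end -> start; reverse in place
    for a in range(n_ops // 2):
        t = ops[a]
        ops[a] = ops[n_ops - 1 - a]
        ops[n_ops - 1 - a] = t
    return best, read_start, read_end, ref_start, ref_end, ops, n_ops, touched


@nb.njit(cache=True, nogil=True)
def accumulate_pileup(counts, clean_counts, op_codes, op_lens, ref_start, read_start,
                      seq_codes, indel_radius):
    """Add one alignment's columns into ``counts`` (L x 5 int64: A, C, G, T,
    deletion; insertions are skipped here). ``clean_counts`` (L x 4)
    additionally receives only base columns at least ``indel_radius``
    reference positions away from every indel in this read — the
    indel-realignment exclusion that keeps substitution evidence clean.
    """
    n_ops = op_codes.size
    # collect indel exclusion intervals in ref coords (ordered by construction)
    iv_lo = np.empty(n_ops, np.int64)
    iv_hi = np.empty(n_ops, np.int64)
    niv = 0
    r = ref_start
    for t in range(n_ops):
        op = op_codes[t]
        ln = op_lens[t]
        if op == OP_INS:
            iv_lo[niv] = r - indel_radius
            iv_hi[niv] = r + indel_radius
            niv += 1
        elif op == OP_DEL:
            iv_lo[niv] = r - indel_radius
            iv_hi[niv] = r + ln + indel_radius
            niv += 1
            r += ln
        elif op == OP_MATCH or op == OP_MISMATCH:
            r += ln
    r = ref_start
    q = read_start
    ptr = 0
    for t in range(n_ops):
        op = op_codes[t]
        ln = op_lens[t]
        if op == OP_MATCH or op == OP_MISMATCH:
            for u in range(ln):
                pos = r + u
                c = seq_codes[q + u]
                if c < 4:  # skip N
                    counts[pos, c] += 1
                    while ptr < niv and iv_hi[ptr] <= pos:
                        ptr += 1
                    if not (ptr < niv and iv_lo[ptr] <= pos):
                        clean_counts[pos, c] += 1
            r += ln
            q += ln
        elif op == OP_DEL:
            for u in range(ln):
                counts[r + u, 4] += 1
            r += ln
        else:
            q += ln
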