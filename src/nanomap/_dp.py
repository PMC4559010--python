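"""Numba kernels for ordered-label dynamic-programming alignment.

The DP state is "query label i matched to reference label j". A transition
from state (p, t) to (i, j) earns the match bonus, pays a Gaussian sizing
term on the gap disagreement, and pays per-label skip penalties for the
reference labels t+1..j-1 (missed / FN-like) and query labels p+1..i-1
(spurious / FP-like). Alignments are local: any state may start a chain at
``bonus`` and the best-scoring cell anywhere wins. The predecessor search
window ``W`` bounds how many labels may be skipped between consecutive
matches.

Ties break deterministically toward the earliest cell/predecessor in row-
major order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dp_score", "dp_align", "batch_pair_scores"]


@njit(cache=True)
def _fill(q, r, fp_pen, fn_pen, bonus, two_s2, min_gap, W, H, Pi, Pj):
    nq = q.shape[0]
    nr = r.shape[0]
    best = 0.0
    bi = -1
    bj = -1
    for i in range(nq):
        for j in range(nr):
            s = bonus
            pi = -1
            pj = -1
            p0 = i - W
            if p0 < 0:
                p0 = 0
            t0 = j - W
            if t0 < 0:
                t0 = 0
            for p in range(p0, i):
                dq = q[i] - q[p]
                for t in range(t0, j):
                    dr = r[j] - r[t]
                    den = dr if dr > min_gap else min_gap
                    diff = dr - dq
                    sz = diff * diff / (two_s2 * den)
                    cand = H[p, t] + bonus - sz - fn_pen * (j - t - 1) - fp_pen * (i - p - 1)
                    if cand > s + 1e-12:
                        s = cand
                        pi = p
                        pj = t
            H[i, j] = s
            Pi[i, j] = pi
            Pj[i, j] = pj
            if s > best + 1e-12:
                best = s
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _fill_score(q, r, fp_pen, fn_pen, bonus, two_s2, min_gap, W, H):
    nq = q.shape[0]
    nr = r.shape[0]
    best = 0.0
    for i in range(nq):
        for j in range(nr):
            s = bonus
            p0 = i - W
            if p0 < 0:
                p0 = 0
            t0 = j - W
            if t0 < 0:
                t0 = 0
            for p in range(p0, i):
                dq = q[i] - q[p]
                for t in range(t0, j):
                    dr = r[j] - r[t]
                    den = dr if dr > min_gap else min_gap
                    diff = dr - dq
                    sz = diff * diff / (two_s2 * den)
                    cand = H[p, t] + bonus - sz - fn_pen * (j - t - 1) - fp_pen * (i - p - 1)
                    if cand > s:
                        s = cand
            H[i, j] = s
            if s > best:
                best = s
    return best


def dp_score(q: np.ndarray, r: np.ndarray, fp_pen: float, fn_pen: float,
             bonus: float, two_s2: float, min_gap: float, W: int) -> float:
    """Best local alignment score of query labels ``q`` vs reference ``r``."""
    nq, nr = len(q), len(r)
    if nq == 0 or nr == 0:
        return 0.0
    H = np.empty((nq, nr), dtype=np.float64)
    return float(_fill_score(np.ascontiguousarray(q, dtype=np.float64),
                             np.ascontiguousarray(r, dtype=np.float64),
                             fp_pen, fn_pen, bonus, two_s2, min_gap, W, H))


def dp_align(q: np.ndarray, r: np.ndarray, fp_pen: float, fn_pen: float,
             bonus: float, two_s2: float, min_gap: float, W: int):
    """Best local alignment with traceback.

    Returns ``(score, qi, rj)`` where ``qi``/``rj`` are the matched index
    arrays in ascending order (empty when both sides are empty).
    """
    nq, nr = len(q), len(r)
    if nq == 0 or nr == 0:
        return 0.0, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    H = np.empty((nq, nr), dtype=np.float64)
    Pi = np.empty((nq, nr), dtype=np.int32)
    Pj = np.empty((nq, nr), dtype=np.int32)
    best, bi, bj = _fill(np.ascontiguousarray(q, dtype=np.float64),
                         np.ascontiguousarray(r, dtype=np.float64),
                         fp_pen, fn_pen, bonus, two_s2, min_gap, W, H, Pi, Pj)
    qi = []
    rj = []
    i, j = bi, bj
    while i >= 0 and j >= 0:
        qi.append(i)
        rj.append(j)
        i, j = int(Pi[i, j]), int(Pj[i, j])
    qi.reverse()
    rj.reverse()
    return float(best), np.array(qi, dtype=np.int64), np.array(rj, dtype=np.int64)


@njit(cache=True)
def _batch_scores(flat, starts, counts, lengths, pa, pb,
                  fp_pen, fn_pen, bonus, two_s2, min_gap, W, max_n):
    n_pairs = pa.shape[0]
    out = np.empty(n_pairs, dtype=np.float64)
    H = np.empty((max_n, max_n), dtype=np.float64)
    qbuf = np.empty(max_n, dtype=np.float64)
    for k in range(n_pairs):
        a = pa[k]
        b = pb[k]
        na = counts[a]
        nb = counts[b]
        qa = flat[starts[a]:starts[a] + na]
        qb = flat[starts[b]:starts[b] + nb]
        # forward orientation
        s_fwd = _fill_score(qa, qb, fp_pen, fn_pen, bonus, two_s2, min_gap, W, H[:na, :nb])
        # reversed query orientation
        La = lengths[a]
        for x in range(na):
            qbuf[x] = La - qa[na - 1 - x]
        s_rev = _fill_score(qbuf[:na], qb, fp_pen, fn_pen, bonus, two_s2, min_gap, W,
                            H[:na, :nb])
        out[k] = s_fwd if s_fwd >= s_rev else s_rev
    return out


def batch_pair_scores(label_lists, lengths, pairs, fp_pen, fn_pen, bonus,
                      two_s2, min_gap, W):
    """Best orientation-maximized DP score for each (a, b) index pair.

    ``label_lists`` is a sequence of 1-D ascending label arrays;
    ``lengths`` the molecule lengths; ``pairs`` an (n, 2) integer array.
    """
    pairs = np.asarray(pairs, dtype=np.int64)
    if len(pairs) == 0:
        return np.empty(0, dtype=np.float64)
    counts = np.array([len(x) for x in label_lists], dtype=np.int64)
    starts = np.zeros(len(label_lists) + 1, dtype=np.int64)
    np.cumsum(counts, out=starts[1:])
    flat = np.concatenate([np.asarray(x, dtype=np.float64) for x in label_lists]) \
        if counts.sum() else np.empty(0, dtype=np.float64)
    max_n = int(counts.max()) if len(counts) else 1
    return _batch_scores(flat, starts[:-1], counts,
                         np.asarray(lengths, dtype=np.float64),
                         pairs[:, 0].copy(), pairs[:, 1].copy(),
                         fp_pen, fn_pen, bonus, two_s2, min_gap, W, max(max_n, 1))
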