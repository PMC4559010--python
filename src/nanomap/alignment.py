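"""Ordered-label map alignment with FP/FN-aware scoring.

Aligns a query label map (an in-silico digested sequence or a consensus
map) to a reference map by dynamic programming over label-pair states.
Matching two consecutive label pairs pays a Gaussian sizing term on the gap
disagreement; skipping reference labels pays the missed-label (FN) penalty
and skipping query labels pays the spurious-label (FP) penalty, both
derived as negative log probabilities from the platform error rates
(-FP 1.5 -FN 0.15 by default). Alignments are local because consensus maps
cover sequences only partially.

The mapping length ratio is the aligned query span divided by the query's
total length; since the flanking regions before the first and after the
last label can never be matched, a ratio of at least 0.95 counts as a
"thorough" alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _dp
from .models import AlignParams, CmapDataset, LabelMap, ValidationError

__all__ = [
    "Alignment",
    "align_maps",
    "align_label_arrays",
    "brute_force_align",
    "mapping_length_ratio",
    "batch_align",
    "BatchResult",
    "estimate_fp_rate",
    "estimate_bpp",
]

THOROUGH_RATIO = 0.95


@dataclass
class Alignment:
    """A site pairing between a query map and a reference map."""

    query_id: str
    ref_id: str
    orientation: str  # "+" or "-"
    pairs: List[Tuple[int, int]]  # (query label index, ref label index)
    score: float
    query_length: float
    ref_length: float
    matched_query_pos: np.ndarray  # original query coordinates, ref order
    matched_ref_pos: np.ndarray
    query_span: float = 0.0
    ref_span: float = 0.0
    n_query_unmatched: int = 0
    n_ref_unmatched: int = 0
    mapping_length_ratio: float = 0.0
    thorough: bool = False
    confidence: float = 0.0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _score_args(params: AlignParams) -> Tuple[float, float, float, float, float, int]:
    s0 = max(params.sizing_sd_scale, 1e-6)
    return (
        params.fp_penalty,
        params.fn_penalty,
        params.bonus,
        2.0 * s0 * s0,
        max(params.resolution_bp, 1.0),
        params.max_skip,
    )


def _oriented_query(labels: np.ndarray, length: float, orientation: str) -> np.ndarray:
    if orientation == "+":
        return labels
    return (length - labels)[::-1]


def align_label_arrays(
    q_labels: np.ndarray,
    q_length: float,
    r_labels: np.ndarray,
    params: AlignParams,
) -> Tuple[float, str, np.ndarray, np.ndarray]:
    """Best local alignment over both orientations.

    Returns ``(score, orientation, qk, rj)`` where ``qk`` are matched query
    indices in *oriented* index space (ascending) and ``rj`` matched
    reference indices (ascending). Ties prefer the ``+`` orientation.
    """
    args = _score_args(params)
    q_fwd = np.asarray(q_labels, dtype=float)
    s_fwd, qi_f, rj_f = _dp.dp_align(q_fwd, r_labels, *args)
    q_rev = _oriented_query(q_fwd, q_length, "-")
    s_rev, qi_r, rj_r = _dp.dp_align(q_rev, r_labels, *args)
    if s_rev > s_fwd + 1e-9:
        return s_rev, "-", qi_r, rj_r
    return s_fwd, "+", qi_f, rj_f


def _build_alignment(
    query: LabelMap,
    ref: LabelMap,
    score: float,
    orientation: str,
    qk: np.ndarray,
    rj: np.ndarray,
) -> Alignment:
    nq = query.n_labels
    q_orient = _oriented_query(np.asarray(query.labels, dtype=float), query.length, orientation)
    r_labels = np.asarray(ref.labels, dtype=float)

    # oriented -> original index
    if orientation == "+":
        orig_idx = qk
    else:
        orig_idx = nq - 1 - qk

    matched_q_orient = q_orient[qk]
    matched_r = r_labels[rj]
    pairs = [(int(a), int(b)) for a, b in zip(orig_idx, rj)]

    k_first, k_last = int(qk[0]), int(qk[-1])
    j_first, j_last = int(rj[0]), int(rj[-1])
    query_span = float(matched_q_orient[-1] - matched_q_orient[0])
    ref_span = float(matched_r[-1] - matched_r[0])
    n_q_un = (k_last - k_first + 1) - len(qk)
    n_r_un = (j_last - j_first + 1) - len(rj)

    # aligned span extended by half the gap to the next unmatched label, or
    # by the full flank when the terminal matched label is the terminal label
    left = q_orient[k_first] if k_first == 0 else 0.5 * (q_orient[k_first] - q_orient[k_first - 1])
    right = (query.length - q_orient[k_last]) if k_last == nq - 1 \
        else 0.5 * (q_orient[k_last + 1] - q_orient[k_last])
    ratio = min(1.0, max(0.0, (query_span + left + right) / query.length))

    matched_q_orig = np.asarray(query.labels, dtype=float)[orig_idx]
    return Alignment(
        query_id=query.id,
        ref_id=ref.id,
        orientation=orientation,
        pairs=pairs,
        score=float(score),
        query_length=float(query.length),
        ref_length=float(ref.length),
        matched_query_pos=matched_q_orig,
        matched_ref_pos=matched_r,
        query_span=query_span,
        ref_span=ref_span,
        n_query_unmatched=int(n_q_un),
        n_ref_unmatched=int(n_r_un),
        mapping_length_ratio=ratio,
        thorough=ratio >= THOROUGH_RATIO,
    )


def align_maps(
    query: LabelMap,
    ref: LabelMap,
    params: AlignParams = AlignParams(),
    compute_confidence: bool = True,
    apply_site_filter: bool = True,
) -> Optional[Alignment]:
    """Best local alignment of ``query`` to ``ref``; None if below threshold.

    Queries with fewer than ``min_query_sites`` labels are filtered (None)
    when ``apply_site_filter`` is set, mirroring the "more than 6 nicking
    sites" rule used for sequence-to-map alignment.
    """
    if apply_site_filter and query.n_labels < params.min_query_sites:
        return None
    if query.n_labels == 0 or ref.n_labels == 0:
        return None
    score, orientation, qk, rj = align_label_arrays(
        np.asarray(query.labels, dtype=float), query.length,
        np.asarray(ref.labels, dtype=float), params)
    if len(qk) == 0 or score < params.min_score:
        return None
    aln = _build_alignment(query, ref, score, orientation, qk, rj)
    if compute_confidence:
        aln.confidence = _confidence(query, ref, aln, params)
    return aln


def _confidence(query: LabelMap, ref: LabelMap, best: Alignment,
                params: AlignParams) -> float:
    """Score margin over the best alignment disjoint from the winner's span."""
    rj = sorted(j for _, j in best.pairs)
    j_first, j_last = rj[0], rj[-1]
    r_labels = np.asarray(ref.labels, dtype=float)
    second = 0.0
    for part in (r_labels[:j_first], r_labels[j_last + 1:]):
        if len(part) == 0:
            continue
        s, _, _, _ = align_label_arrays(
            np.asarray(query.labels, dtype=float), query.length, part, params)
        second = max(second, s)
    return max(0.0, best.score - second)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _pairing_score(q: np.ndarray, r: np.ndarray, qi: Sequence[int], rj: Sequence[int],
                   params: AlignParams) -> float:
    fp_pen, fn_pen, bonus, two_s2, min_gap, _ = _score_args(params)
    s = bonus * len(qi)
    for (a0, b0), (a1, b1) in zip(zip(qi, rj), zip(qi[1:], rj[1:])):
        dq = q[a1] - q[a0]
        dr = r[b1] - r[b0]
        den = max(dr, min_gap)
        s -= (dr - dq) ** 2 / (two_s2 * den)
        s -= fn_pen * (b1 - b0 - 1)
        s -= fp_pen * (a1 - a0 - 1)
    return s


def brute_force_align(
    query: LabelMap,
    ref: LabelMap,
    params: AlignParams = AlignParams(),
) -> Tuple[float, str, List[Tuple[int, int]]]:
    """Exhaustive enumeration of all monotone pairings, both orientations.

    Independent oracle for :func:`align_maps` on tiny instances; returns
    ``(best score, orientation, pairs in oriented index space)``. The empty
    pairing (score 0) is allowed.
    """
    nq, nr = query.n_labels, ref.n_labels
    if nq > 8 or nr > 8:
        raise ValidationError("brute_force_align is limited to <= 8 labels per side")
    r = np.asarray(ref.labels, dtype=float)
    best = (0.0, "+", [])
    for orientation in ("+", "-"):
        q = _oriented_query(np.asarray(query.labels, dtype=float), query.length, orientation)
        for k in range(1, min(nq, nr) + 1):
            for qi in itertools.combinations(range(nq), k):
                for rj in itertools.combinations(range(nr), k):
                    s = _pairing_score(q, r, qi, rj, params)
                    if s > best[0] + 1e-12:
                        best = (s, orientation, list(zip(qi, rj)))
    return best


def mapping_length_ratio(alignment: Alignment, query_total_length: Optional[float] = None) -> float:
    """Aligned query span over the query's total length, clamped to [0, 1]."""
    if query_total_length is None or query_total_length == alignment.query_length:
        return alignment.mapping_length_ratio
    span = alignment.mapping_length_ratio * alignment.query_length
    return min(1.0, max(0.0, span / query_total_length))


# ---------------------------------------------------------------------------
# Batch alignment
# ---------------------------------------------------------------------------


@dataclass
class BatchResult:
    """Best-per-query alignments and mapping-length-ratio summary."""

    alignments: Dict[str, Alignment]
    n_queries: int
    n_retained: int  # queries passing the >= min_query_sites filter
    n_aligned: int
    frac_ratio_ge: Dict[float, float]

    def ratios(self) -> np.ndarray:
        return np.array([a.mapping_length_ratio for a in self.alignments.values()])


def batch_align(
    queries: Union[CmapDataset, Sequence[LabelMap]],
    refs: Union[CmapDataset, Sequence[LabelMap]],
    params: AlignParams = AlignParams(),
    thresholds: Tuple[float, ...] = (0.7, 0.8, 0.95),
) -> BatchResult:
    """Align every query to every reference, keeping the best per query.

    Following standard practice only the highest-confidence alignment of
    each query is retained. Summary fractions are over retained queries
    (those passing the label-count filter); unaligned queries count as
    ratio 0.
    """
    q_list = queries.maps if isinstance(queries, CmapDataset) else list(queries)
    r_list = refs.maps if isinstance(refs, CmapDataset) else list(refs)
    best: Dict[str, Alignment] = {}
    n_retained = 0
    for q in q_list:
        if q.n_labels < params.min_query_sites:
            continue
        n_retained += 1
        chosen: Optional[Alignment] = None
        for r in r_list:
            aln = align_maps(q, r, params, compute_confidence=True, apply_site_filter=False)
            if aln is None:
                continue
            if chosen is None or (aln.confidence, aln.score) > (chosen.confidence, chosen.score):
                chosen = aln
        if chosen is not None:
            best[q.id] = chosen
    frac = {}
    for t in thresholds:
        n_pass = sum(1 for a in best.values() if a.mapping_length_ratio >= t)
        frac[t] = n_pass / n_retained if n_retained else 0.0
    return BatchResult(
        alignments=best,
        n_queries=len(q_list),
        n_retained=n_retained,
        n_aligned=len(best),
        frac_ratio_ge=frac,
    )


# ---------------------------------------------------------------------------
# Rate estimators
# ---------------------------------------------------------------------------


def estimate_fp_rate(alignments: Iterable[Alignment]) -> Optional[float]:
    """Unmatched query labels inside aligned spans per 100 kb of aligned span.

    Reconstruction of the alignment-based false-positive rate estimate:
    query labels that fall strictly inside the aligned interval but pair
    with no reference site are counted as false labels.
    """
    total_unmatched = 0
    total_span = 0.0
    for aln in alignments:
        total_unmatched += aln.n_query_unmatched
        total_span += aln.query_span
    if total_span <= 0:
        return None
    return total_unmatched / total_span * 100_000.0


def estimate_bpp(alignments: Iterable[Alignment], nominal_bpp: float = 500.0) -> Optional[float]:
    """Effective bases-per-pixel scale from matched gap regression.

    Least-squares slope (through the origin) of matched query gaps on
    matched reference gaps, times the nominal pixel scale: a molecule
    stretch of 1.008 at a 500 bp pixel reads out as ~504 bp/pixel.
    """
    num = 0.0
    den = 0.0
    for aln in alignments:
        if aln.n_pairs < 2:
            continue
        dq = np.abs(np.diff(aln.matched_query_pos))
        dr = np.abs(np.diff(aln.matched_ref_pos))
        num += float(np.dot(dq, dr))
        den += float(np.dot(dr, dr))
    if den <= 0:
        return None
    return num / den * nominal_bpp
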