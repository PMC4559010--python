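"""Consensus genome-map assembly from labelled molecules.

The assembler follows the classic overlap-layout-consensus scheme adapted
to ordered label patterns:

1. *cluster*  — molecules are compared pairwise by overlap alignment of
   their label patterns (both orientations); 1 - normalized score is a
   distance in [0, 1], and hierarchical clustering cut at ``cluster_cut``
   groups molecules that tile the same genomic region. An inverted index of
   quantized gap k-mers prefilters which pairs are worth aligning.
2. *layout*   — within a cluster, the longest molecule seeds a coordinate
   frame; remaining molecules are placed best-link-first through the
   overlap graph, each by a signed affine fit (scale + offset, negative
   scale = reverse orientation) to its strongest already-placed neighbour.
3. *consensus* — anchored label positions are pooled, their density fitted
   with Gaussian kernels, and local maxima with sufficient molecule support
   become consensus labels; peaks closer than the labelling resolution are
   merged.

All stages are deterministic given the input order and parameters.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.signal import find_peaks

from . import _dp
from .alignment import align_label_arrays
from .models import (
    AssemblyParams,
    BnxDataset,
    CmapDataset,
    ConsensusMap,
    Molecule,
    ValidationError,
)
from .stats import n50

__all__ = [
    "mol_distance",
    "candidate_pairs",
    "pairwise_distances",
    "cluster_molecules",
    "Placement",
    "anchor_cluster",
    "call_consensus",
    "assemble",
    "AssemblyReport",
    "depth_titration",
    "DepthTitrationResult",
]


def _dp_args(params: AssemblyParams):
    a = params.align
    s0 = max(a.sizing_sd_scale, 1e-6)
    return (a.fp_penalty, a.fn_penalty, a.bonus, 2.0 * s0 * s0,
            max(a.resolution_bp, 1.0), a.max_skip)


def _norm_distance(score: float, na: int, nb: int, bonus: float) -> float:
    if na < 2 or nb < 2:
        return 1.0
    d = 1.0 - max(score, 0.0) / (bonus * min(na, nb))
    return float(min(1.0, max(0.0, d)))


def mol_distance(mol_a: Molecule, mol_b: Molecule,
                 params: AssemblyParams = AssemblyParams()) -> float:
    """Label-pattern distance in [0, 1]: 1 - normalized overlap score.

    Both orientations are tried; 0 for identical patterns; molecules with
    fewer than 2 labels are assigned the maximal distance 1.0.
    """
    if mol_a.n_labels < 2 or mol_b.n_labels < 2:
        return 1.0
    args = _dp_args(params)
    scores = _dp.batch_pair_scores(
        [np.asarray(mol_a.labels, float), np.asarray(mol_b.labels, float)],
        [mol_a.length, mol_b.length], np.array([[0, 1]]), *args)
    return _norm_distance(float(scores[0]), mol_a.n_labels, mol_b.n_labels,
                          params.align.bonus)


# ---------------------------------------------------------------------------
# Overlap-candidate prefilter
# ---------------------------------------------------------------------------


def _gap_kmers(labels: np.ndarray, k: int, quantum: float) -> Set[Tuple[int, ...]]:
    gaps = np.diff(labels)
    keys: Set[Tuple[int, ...]] = set()
    for g in (gaps, gaps[::-1]):
        if len(g) < k:
            continue
        bins = np.floor(g / quantum).astype(np.int64)
        for i in range(len(bins) - k + 1):
            keys.add(tuple(bins[i:i + k]))
    return keys


def _neighbor_keys(key: Tuple[int, ...]):
    from itertools import product
    for deltas in product((-1, 0, 1), repeat=len(key)):
        yield tuple(b + d for b, d in zip(key, deltas))


def candidate_pairs(label_lists: Sequence[np.ndarray], params: AssemblyParams) -> np.ndarray:
    """Molecule index pairs plausibly sharing an overlap.

    Two molecules are candidates when they share at least
    ``min_shared_fingerprints`` quantized gap k-mers (either orientation,
    with one-bin tolerance per gap). Over-popular fingerprints (repetitive
    gap patterns) are skipped.
    """
    n = len(label_lists)
    k = params.fingerprint_k
    q = params.fingerprint_quantum
    index: Dict[Tuple[int, ...], List[int]] = defaultdict(list)
    key_sets = []
    for i, labels in enumerate(label_lists):
        keys = _gap_kmers(np.asarray(labels, float), k, q)
        key_sets.append(keys)
        for key in keys:
            index[key].append(i)
    bucket_cap = max(150, int(0.1 * n))
    counts: Dict[Tuple[int, int], int] = defaultdict(int)
    for i, keys in enumerate(key_sets):
        probed: Set[Tuple[int, ...]] = set()
        for key in keys:
            for nb in _neighbor_keys(key):
                if nb in probed:
                    continue
                probed.add(nb)
                bucket = index.get(nb)
                if bucket is None or len(bucket) > bucket_cap:
                    continue
                for j in bucket:
                    if j > i:
                        counts[(i, j)] += 1
    # keep a pair when it is among either molecule's strongest-sharing partners
    per_mol: Dict[int, List[Tuple[int, int, int]]] = defaultdict(list)
    for (i, j), c in counts.items():
        if c >= params.min_shared_fingerprints:
            per_mol[i].append((c, i, j))
            per_mol[j].append((c, i, j))
    kept: Set[Tuple[int, int]] = set()
    cap = params.max_candidates_per_mol
    for m, lst in per_mol.items():
        lst.sort(key=lambda e: (-e[0], e[1], e[2]))
        for _c, i, j in lst[:cap]:
            kept.add((i, j))
    pairs = sorted(kept)
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def pairwise_distances(
    molecules: Sequence[Molecule],
    params: AssemblyParams = AssemblyParams(),
    pairs: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, List[Tuple[int, int, float, float]]]:
    """Condensed distance matrix plus scored candidate edges.

    Non-candidate pairs get the maximal distance 1.0. Returns
    ``(condensed, edges)`` with edges ``(i, j, score, distance)``.
    """
    n = len(molecules)
    label_lists = [np.asarray(m.labels, float) for m in molecules]
    lengths = [m.length for m in molecules]
    if pairs is None:
        usable = [l if len(l) >= 2 else np.empty(0) for l in label_lists]
        pairs = candidate_pairs(usable, params)
    condensed = np.ones(n * (n - 1) // 2, dtype=float)
    edges: List[Tuple[int, int, float, float]] = []
    if len(pairs):
        scores = _dp.batch_pair_scores(label_lists, lengths, pairs, *_dp_args(params))
        bonus = params.align.bonus
        for (i, j), s in zip(pairs, scores):
            d = _norm_distance(float(s), len(label_lists[i]), len(label_lists[j]), bonus)
            edges.append((int(i), int(j), float(s), d))
            idx = n * i - (i * (i + 1)) // 2 + (j - i - 1)
            condensed[idx] = d
    return condensed, edges


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_molecules(
    distances: np.ndarray,
    params: AssemblyParams = AssemblyParams(),
) -> Tuple[List[List[int]], List[int]]:
    """Agglomerative clustering of the distance matrix, cut at ``cluster_cut``.

    Accepts a condensed or square symmetric matrix. Returns
    ``(retained clusters, discarded molecule indices)``; clusters smaller
    than ``min_molecules_per_map`` are discarded.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim == 2:
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
            raise ValidationError("distance matrix must be square and symmetric")
        n = D.shape[0]
        condensed = D[np.triu_indices(n, k=1)]
    else:
        condensed = D
        n = int(round((1 + math.sqrt(1 + 8 * len(D))) / 2))
    if n == 0:
        return [], []
    if n == 1:
        labels = np.array([1])
    else:
        Z = scipy_linkage(condensed, method=params.linkage)
        labels = fcluster(Z, t=params.cluster_cut, criterion="distance")
    groups: Dict[int, List[int]] = defaultdict(list)
    for i, c in enumerate(labels):
        groups[int(c)].append(i)
    clusters: List[List[int]] = []
    discarded: List[int] = []
    for c in sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c]))):
        members = groups[c]
        if len(members) >= params.min_molecules_per_map:
            clusters.append(members)
        else:
            discarded.extend(members)
    return clusters, sorted(discarded)


# ---------------------------------------------------------------------------
# Layout (anchoring)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """A molecule's signed-affine placement on the cluster axis.

    layout(x) = scale * x + offset; negative scale means the molecule is
    reverse-oriented on the layout.
    """

    index: int
    scale: float
    offset: float

    @property
    def orientation(self) -> str:
        return "+" if self.scale >= 0 else "-"

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(x, float) + self.offset

    def interval(self, length: float) -> Tuple[float, float]:
        a, b = self.offset, self.scale * length + self.offset
        return (a, b) if a <= b else (b, a)


def _tls_scale(xq: np.ndarray, xr: np.ndarray) -> Optional[float]:
    """Major-axis (total least squares) scale estimate |d xr / d xq|.

    Symmetric in the noise of both coordinate sets, so it avoids the
    regression-dilution bias of ordinary least squares (which would
    systematically shrink chained layouts).
    """
    xq = np.asarray(xq, float)
    xr = np.asarray(xr, float)
    sx = float(xq.std())
    sy = float(xr.std())
    if sx <= 0 or sy <= 0:
        return None
    return sy / sx


def _unit_placement(xq: np.ndarray, xr: np.ndarray, orientation: str,
                    max_scale_dev: float) -> Optional[Tuple[float, float]]:
    """Signed unit-scale placement xr ~ s*xq + t with s in {+1, -1}.

    Molecule stretch is a shared, near-unit factor; per-molecule scale
    *fitting* injects multiplicative noise that compounds along the layout,
    so placements use unit scale and the fitted scale only as a sanity
    gate on the link.
    """
    scale = _tls_scale(xq, xr)
    if scale is None or abs(scale - 1.0) > max_scale_dev:
        return None
    s = 1.0 if orientation == "+" else -1.0
    t = float(np.mean(xr) - s * np.mean(xq))
    return s, t


def _pair_placement(mol: Molecule, ref_labels: np.ndarray, params: AssemblyParams
                    ) -> Optional[Tuple[float, float, float]]:
    """(score, scale, offset) mapping mol coords onto ref coords, or None.

    Besides the score/pair-count/scale gates, the winning orientation must
    beat the opposite orientation by ``orientation_margin``: an ambiguous
    orientation at a weak link would mirror everything placed through it.
    """
    args = _dp_args(params)
    q = np.asarray(mol.labels, float)
    r = np.asarray(ref_labels, float)
    s_fwd, qi_f, rj_f = _dp.dp_align(q, r, *args)
    q_rev = (mol.length - q)[::-1]
    s_rev, qi_r, rj_r = _dp.dp_align(q_rev, r, *args)
    if s_rev > s_fwd + 1e-9:
        score, orientation, qk, rj = s_rev, "-", qi_r, rj_r
        margin = s_rev - s_fwd
    else:
        score, orientation, qk, rj = s_fwd, "+", qi_f, rj_f
        margin = s_fwd - s_rev
    if score < params.min_anchor_score or len(qk) < params.min_anchor_pairs:
        return None
    if margin < params.orientation_margin:
        return None
    if orientation == "+":
        orig = qk
    else:
        orig = mol.n_labels - 1 - qk
    fit = _unit_placement(q[orig], r[rj], orientation, params.max_scale_dev)
    if fit is None:
        return None
    s, t = fit
    return score, s, t, len(qk)


def anchor_cluster(
    molecules: Sequence[Molecule],
    params: AssemblyParams = AssemblyParams(),
    edges: Optional[List[Tuple[int, int, float, float]]] = None,
) -> Tuple[List[Placement], List[int]]:
    """Place cluster molecules on a shared axis (layout step).

    The longest molecule (ties: lexicographic id) seeds the frame at
    scale +1, offset 0. Remaining molecules are placed best-overlap-first:
    repeatedly, the strongest candidate edge between a placed and an
    unplaced molecule is realigned with traceback and the unplaced molecule
    receives the composed signed-affine placement. Molecules that cannot be
    linked (or whose fits fail the score/scale gates) are set aside.
    """
    n = len(molecules)
    if n == 0:
        return [], []
    if n == 1:
        return [Placement(0, 1.0, 0.0)], []
    if edges is None:
        _, edges = pairwise_distances(molecules, params)
    adj: Dict[int, List[Tuple[float, int]]] = defaultdict(list)
    for i, j, score, _d in edges:
        adj[i].append((score, j))
        adj[j].append((score, i))

    seed = min(range(n), key=lambda i: (-molecules[i].length, molecules[i].id))
    placements: Dict[int, Placement] = {seed: Placement(seed, 1.0, 0.0)}
    span_lo, span_hi = 0.0, float(molecules[seed].length)
    heap: List[Tuple[float, str, int, int]] = []

    def push_edges(placed_idx: int) -> None:
        for score, j in adj[placed_idx]:
            if j not in placements:
                heapq.heappush(heap, (-score, molecules[j].id, j, placed_idx))

    push_edges(seed)
    retry_rounds = 0
    while heap:
        neg_score, _mid, cand, _via = heapq.heappop(heap)
        if not heap or cand in placements:
            # when the frontier drains, give every remaining molecule one
            # more look at the now-mature layout (placements accumulated
            # since its last attempt may tip the vote)
            if not heap and retry_rounds < 8:
                progress_marker = len(placements)
                for u in range(n):
                    if u not in placements and any(j in placements for _sc, j in adj[u]):
                        heapq.heappush(heap, (0.0, molecules[u].id, u, -1))
                retry_rounds += 1
                if cand in placements:
                    continue
            elif cand in placements:
                continue
        # consult the strongest placed neighbours and vote: a single noisy
        # link must not be able to mirror or teleport a molecule
        nbs = sorted(((sc, j) for sc, j in adj[cand] if j in placements),
                     key=lambda e: -e[0])[:params.max_place_checks]
        preds = []  # (weight, scale, offset, n_pairs)
        for sc, j in nbs:
            rel = _pair_placement(molecules[cand], molecules[j].labels, params)
            if rel is None:
                continue
            rscore, s_rel, t_rel, npairs = rel
            ref = placements[j]
            preds.append((rscore, ref.scale * s_rel,
                          ref.scale * t_rel + ref.offset, npairs))
            if len(preds) >= 3:
                break
        if not preds:
            continue  # a later heap entry may retry once more neighbours exist
        pos_w = sum(p[0] for p in preds if p[1] > 0)
        neg_w = sum(p[0] for p in preds if p[1] < 0)
        sign = 1.0 if pos_w >= neg_w else -1.0
        group = [p for p in preds if (p[1] > 0) == (sign > 0)]
        offsets = np.array([p[2] for p in group])
        med = float(np.median(offsets))
        keep = [p for p in group if abs(p[2] - med) <= params.placement_agree_tol]
        # a single link may be a spurious high-scoring match that would
        # teleport the molecule (and seed a whole arm at the wrong place):
        # demand two independent agreeing links whenever the molecule has
        # more than one candidate neighbour at all
        required = 1 if len(placements) < 3 else min(2, len(adj[cand]))
        if len(keep) < required:
            continue
        mol_len = molecules[cand].length
        wsum = sum(p[0] for p in keep)
        offset = sum(p[0] * p[2] for p in keep) / wsum
        scale = sum(p[0] * p[1] for p in keep) / wsum
        tentative = Placement(cand, scale, offset)
        iv = tentative.interval(mol_len)
        extension = max(0.0, span_lo - iv[0]) + max(0.0, iv[1] - span_hi)
        if extension < 0.2 * mol_len:
            # an interior placement must be a near-duplicate of covered
            # territory: a weakly matched interior fit is the signature of
            # a spurious locus-level pattern match (teleport)
            best_pairs = max(p[3] for p in keep)
            if best_pairs < 0.5 * molecules[cand].n_labels:
                continue
        if len(keep) == 1 and not _triangle_confirms(
                molecules, adj, placements, cand, keep[0], params):
            continue
        placements[cand] = tentative
        span_lo = min(span_lo, iv[0])
        span_hi = max(span_hi, iv[1])
        push_edges(cand)

    placed = [placements[i] for i in sorted(placements)]
    set_aside = [i for i in range(n) if i not in placements]
    return placed, set_aside


def _triangle_confirms(molecules, adj, placements, cand, pred,
                       params: AssemblyParams, max_witnesses: int = 3) -> bool:
    """Confirm a single-link placement through a third molecule.

    A placement supported by one link alone is checked against witnesses
    adjacent to both the candidate and the link partner: placing the
    witness through the partner and through the candidate's tentative
    placement must agree in orientation and offset. A spurious link almost
    never finds a consistent witness; if witnesses exist but none agree,
    the placement is refused.
    """
    w, scale, offset, _npairs = pred
    tentative = Placement(cand, scale, offset)
    cand_nb = {j for _sc, j in adj[cand]}
    best_via = max(((sc, j) for sc, j in adj[cand] if j in placements),
                   default=None)
    if best_via is None:
        return True
    via = best_via[1]
    via_nb = {j for _sc, j in adj[via]}
    witnesses = sorted(cand_nb & via_nb - {cand, via})[:max_witnesses]
    if not witnesses:
        return True  # nothing to check against (tiny neighbourhood)
    ref = placements[via]
    for z in witnesses:
        rel1 = _pair_placement(molecules[z], molecules[via].labels, params)
        rel2 = _pair_placement(molecules[z], molecules[cand].labels, params)
        if rel1 is None or rel2 is None:
            continue
        _s1, a1, b1, _n1 = rel1
        _s2, a2, b2, _n2 = rel2
        p1 = (ref.scale * a1, ref.scale * b1 + ref.offset)
        p2 = (tentative.scale * a2, tentative.scale * b2 + tentative.offset)
        if (p1[0] > 0) == (p2[0] > 0) and abs(p1[1] - p2[1]) <= params.placement_agree_tol:
            return True
    return False


# ---------------------------------------------------------------------------
# Consensus calling
# ---------------------------------------------------------------------------


def _consensus_positions(
    molecules: Sequence[Molecule],
    placements: Sequence[Placement],
    params: AssemblyParams,
) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Peak-call pooled anchored labels in layout coordinates.

    Returns (positions, support, span_start, span_end).
    """
    pooled: List[np.ndarray] = []
    owner: List[np.ndarray] = []
    starts = []
    ends = []
    for p in placements:
        mol = molecules[p.index]
        pos = p.transform(mol.labels)
        pos = np.sort(pos)
        pooled.append(pos)
        owner.append(np.full(len(pos), p.index, dtype=np.int64))
        a, b = p.interval(mol.length)
        starts.append(a)
        ends.append(b)
    positions = np.concatenate(pooled) if pooled else np.empty(0)
    owners = np.concatenate(owner) if owner else np.empty(0, dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    owners = owners[order]
    span_start = float(min(starts))
    span_end = float(max(ends))
    starts_arr = np.sort(np.asarray(starts))
    ends_arr = np.sort(np.asarray(ends))

    if len(positions) == 0:
        return np.empty(0), np.empty(0, dtype=int), span_start, span_end

    step = params.consensus_grid
    bw = params.kde_bandwidth
    grid_lo = span_start - 2 * bw
    nbins = int(np.ceil((span_end + 2 * bw - grid_lo) / step)) + 1
    counts = np.bincount(
        np.clip(((positions - grid_lo) / step).astype(np.int64), 0, nbins - 1),
        minlength=nbins).astype(float)
    half = int(np.ceil(4 * bw / step))
    xs = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (xs / bw) ** 2)
    density = np.convolve(counts, kernel, mode="same")

    peak_idx, _ = find_peaks(density, height=1e-9)
    # support is counted within the kernel scale; the called position is the
    # mean of the nearby labels (falling back to the wider window when a
    # merged flat-topped peak has no labels right at its apex)
    win_sup = max(params.resolution_bp / 2.0, bw)
    win_pos = min(0.6 * bw, params.resolution_bp / 2.0) + 1e-9
    cand_pos: List[float] = []
    cand_sup: List[int] = []
    for pi in peak_idx:
        c = grid_lo + pi * step
        lo = np.searchsorted(positions, c - win_sup, side="left")
        hi = np.searchsorted(positions, c + win_sup, side="right")
        if hi <= lo:
            continue
        sup = len(np.unique(owners[lo:hi]))
        coverage = int(np.searchsorted(starts_arr, c, side="right")
                       - np.searchsorted(ends_arr, c, side="left"))
        coverage = max(coverage, 1)
        required = max(1, int(np.ceil(params.min_peak_support_frac * coverage)))
        if coverage >= 2:
            required = max(required, 2)
        if sup < required:
            continue
        lo2 = np.searchsorted(positions, c - win_pos, side="left")
        hi2 = np.searchsorted(positions, c + win_pos, side="right")
        core = positions[lo2:hi2] if hi2 > lo2 else positions[lo:hi]
        cand_pos.append(float(np.median(core)))
        cand_sup.append(int(sup))

    if not cand_pos:
        return np.empty(0), np.empty(0, dtype=int), span_start, span_end

    order2 = np.argsort(cand_pos, kind="stable")
    pos_sorted = [cand_pos[k] for k in order2]
    sup_sorted = [cand_sup[k] for k in order2]
    # merge peaks closer than the resolution, keeping the better-supported one
    out_pos: List[float] = [pos_sorted[0]]
    out_sup: List[int] = [sup_sorted[0]]
    for p0, s0 in zip(pos_sorted[1:], sup_sorted[1:]):
        if p0 - out_pos[-1] < params.resolution_bp:
            if s0 > out_sup[-1]:
                out_pos[-1] = p0
                out_sup[-1] = s0
        else:
            out_pos.append(p0)
            out_sup.append(s0)
    return np.array(out_pos), np.array(out_sup, dtype=int), span_start, span_end


def _global_offset_adjust(
    molecules: Sequence[Molecule],
    placements: List[Placement],
    edges: List[Tuple[int, int, float, float]],
    params: AssemblyParams,
    max_links_per_mol: int = 6,
) -> List[Placement]:
    """Redistribute chained placement error over the whole overlap graph.

    Initial layout offsets accumulate alignment noise as a random walk along
    the placement tree. Every retained overlap link measures the *relative*
    offset of two placed molecules free of that walk, so solving the
    weighted least-squares problem  min sum_w (m_ij + u_j - u_i)^2  over
    per-molecule offset corrections u (a graph-Laplacian system) removes
    most of the accumulated warp.
    """
    placed = {p.index: p for p in placements}
    if len(placed) < 3:
        return placements
    by_mol: Dict[int, List[Tuple[float, int, int]]] = defaultdict(list)
    for i, j, score, _d in edges:
        if i in placed and j in placed:
            by_mol[i].append((score, i, j))
            by_mol[j].append((score, i, j))
    kept: Set[Tuple[int, int]] = set()
    for m, lst in by_mol.items():
        lst.sort(key=lambda e: -e[0])
        for _s, i, j in lst[:max_links_per_mol]:
            kept.add((i, j))

    order = sorted(placed)
    pos_of = {g: k for k, g in enumerate(order)}
    n = len(order)
    rows: List[Tuple[int, int, float, float]] = []  # (ki, kj, weight, m_ij)
    for i, j in sorted(kept):
        pi, pj = placed[i], placed[j]
        score, orientation, qk, rj = align_label_arrays(
            np.asarray(molecules[i].labels, float), molecules[i].length,
            np.asarray(molecules[j].labels, float), params.align)
        if len(qk) < params.min_anchor_pairs or score < params.min_anchor_score:
            continue
        same_sign = (pi.scale * pj.scale) > 0
        if (orientation == "+") != same_sign:
            continue
        orig = qk if orientation == "+" else molecules[i].n_labels - 1 - qk
        xi = np.asarray(molecules[i].labels, float)[orig]
        xj = np.asarray(molecules[j].labels, float)[rj]
        m_ij = float(np.mean(pj.transform(xj) - pi.transform(xi)))
        if abs(m_ij) > 10 * params.resolution_bp:
            continue  # inconsistent link (wrong repeat copy or bad fit)
        rows.append((pos_of[i], pos_of[j], float(len(qk)), m_ij))
    if len(rows) < n:
        return placements

    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve
    ii: List[int] = []
    jj: List[int] = []
    vv: List[float] = []
    b = np.zeros(n)
    for ki, kj, w, m_ij in rows:
        ii += [ki, kj, ki, kj]
        jj += [ki, kj, kj, ki]
        vv += [w, w, -w, -w]
        b[ki] += w * m_ij
        b[kj] -= w * m_ij
    # gauge fixing: softly pin the mean correction to zero
    for k in range(n):
        ii.append(k)
        jj.append(k)
        vv.append(1e-6)
    L = coo_matrix((vv, (ii, jj)), shape=(n, n)).tocsr()
    u = spsolve(L, b)
    u = u - u.mean()
    return [Placement(p.index, p.scale, p.offset + float(u[pos_of[p.index]]))
            for p in (placed[g] for g in order)]


def _refine_placements(
    molecules: Sequence[Molecule],
    placements: List[Placement],
    params: AssemblyParams,
) -> List[Placement]:
    cons_pos, _sup, _a, _b = _consensus_positions(molecules, placements, params)
    if len(cons_pos) < 3:
        return placements
    span = float(cons_pos[-1] - cons_pos[0]) if len(cons_pos) > 1 else 1.0
    refined: List[Placement] = []
    for p in placements:
        mol = molecules[p.index]
        rel = _pair_placement_to_array(mol, cons_pos, span, params)
        refined.append(Placement(p.index, rel[0], rel[1]) if rel is not None else p)
    return refined


def _pair_placement_to_array(mol: Molecule, ref_labels: np.ndarray, ref_span: float,
                             params: AssemblyParams) -> Optional[Tuple[float, float]]:
    score, orientation, qk, rj = align_label_arrays(
        np.asarray(mol.labels, float), mol.length, np.asarray(ref_labels, float),
        params.align)
    if score < params.min_anchor_score or len(qk) < params.min_anchor_pairs:
        return None
    orig = qk if orientation == "+" else mol.n_labels - 1 - qk
    xq = np.asarray(mol.labels, float)[orig]
    xr = np.asarray(ref_labels, float)[rj]
    # against an averaged (low-noise) consensus a one-shot scale fit is safe:
    # it absorbs the molecule's own stretch without chained-dilution compounding
    scale = _tls_scale(xq, xr)
    if scale is None or abs(scale - 1.0) > params.max_scale_dev:
        return None
    s = scale if orientation == "+" else -scale
    t = float(np.mean(xr) - s * np.mean(xq))
    return s, t


def call_consensus(
    molecules: Sequence[Molecule],
    placements: Sequence[Placement],
    params: AssemblyParams = AssemblyParams(),
    map_id: str = "map_1",
) -> ConsensusMap:
    """Build a consensus map from anchored molecules (consensus step)."""
    if not placements:
        raise ValidationError("call_consensus requires at least one placement")
    pos, sup, span_start, span_end = _consensus_positions(molecules, placements, params)
    length = max(span_end - span_start, 1.0)
    labels = np.clip(pos - span_start, 0.0, length)
    total_mol = sum(abs(p.scale) * molecules[p.index].length for p in placements)
    return ConsensusMap(
        id=map_id,
        length=float(length),
        labels=labels,
        support=sup if len(sup) else np.empty(0, dtype=int),
        mean_depth=float(total_mol / length),
    )


# ---------------------------------------------------------------------------
# Full assembly
# ---------------------------------------------------------------------------


@dataclass
class AssemblyReport:
    """Bookkeeping for one assembly run."""

    n_input: int = 0
    n_filtered_short: int = 0
    n_filtered_degenerate: int = 0
    cluster_sizes: List[int] = field(default_factory=list)
    discarded: List[str] = field(default_factory=list)
    set_aside: List[str] = field(default_factory=list)
    redundant: List[str] = field(default_factory=list)
    placements: Dict[str, List[Placement]] = field(default_factory=dict)


@dataclass
class _MapEntry:
    """A consensus map together with the molecules and placements behind it."""

    mols: List[Molecule]
    placements: List[Placement]
    cmap: ConsensusMap

    def span_start(self) -> float:
        return min(p.interval(self.mols[p.index].length)[0] for p in self.placements)


def _map_to_map_transform(a: "_MapEntry", b: "_MapEntry", params: AssemblyParams,
                          min_pairs: int = 8, min_score: float = 50.0):
    """Signed unit-scale transform from B's layout frame into A's, or None."""
    from .alignment import align_maps as _align_maps
    aln = _align_maps(b.cmap, a.cmap, params.align, compute_confidence=False,
                      apply_site_filter=False)
    if aln is None or aln.n_pairs < min_pairs or aln.score < min_score:
        return None
    fit = _unit_placement(aln.matched_query_pos, aln.matched_ref_pos,
                          aln.orientation, params.max_scale_dev)
    if fit is None:
        return None
    return fit  # map-coordinate transform: pos_A = s * pos_B + t


def _merge_overlapping_maps(entries: List["_MapEntry"],
                            params: AssemblyParams) -> List["_MapEntry"]:
    """Fuse maps whose consensus patterns overlap into single layouts.

    Thin coverage or label deserts can break one genomic region into
    several staggered or duplicated maps; when two consensus maps align
    well, the shorter map's molecules are transformed into the longer
    map's frame, placements are refined against the joint consensus, and
    the consensus is re-called.
    """
    merged = True
    while merged and len(entries) > 1:
        merged = False
        entries.sort(key=lambda e: (-e.cmap.length, e.cmap.id))
        for ia in range(len(entries)):
            for ib in range(ia + 1, len(entries)):
                a, b = entries[ia], entries[ib]
                fit = _map_to_map_transform(a, b, params)
                if fit is None:
                    continue
                s_ab, t_ab = fit
                a0_a = a.span_start()
                a0_b = b.span_start()
                new_placements = list(a.placements)
                offset_idx = len(a.mols)
                for p in b.placements:
                    scale = s_ab * p.scale
                    offset = s_ab * (p.offset - a0_b) + t_ab + a0_a
                    new_placements.append(Placement(p.index + offset_idx, scale, offset))
                joint = _MapEntry(mols=a.mols + b.mols, placements=new_placements,
                                  cmap=a.cmap)
                joint.placements = _refine_placements(joint.mols, joint.placements, params)
                joint.cmap = call_consensus(joint.mols, joint.placements, params,
                                            map_id=a.cmap.id)
                entries[ia] = joint
                del entries[ib]
                merged = True
                break
            if merged:
                break
    return entries


def _purge_redundant(entries: List["_MapEntry"], params: AssemblyParams,
                     sample_size: int = 20, max_refs: int = 4,
                     redundant_frac: float = 0.6
                     ) -> Tuple[List["_MapEntry"], List[str]]:
    """Drop maps that mostly re-assemble a region a longer map already covers.

    Molecules that fail layout voting can re-anchor into small maps
    duplicating an assembled locus. Redundancy is judged at the molecule
    level (robust even when the duplicate's consensus is warped): a map is
    redundant when most of a sample of its member molecules align well to
    a longer kept map.
    """
    args = _dp_args(params)
    order = sorted(entries, key=lambda e: (-e.cmap.length, e.cmap.id))
    kept: List[_MapEntry] = []
    dropped: List[str] = []
    for e in order:
        redundant = False
        member_idx = sorted({p.index for p in e.placements})[:sample_size]
        for ref in kept[:max_refs]:
            r = np.asarray(ref.cmap.labels, float)
            n_hit = 0
            for mi in member_idx:
                mol = e.mols[mi]
                q = np.asarray(mol.labels, float)
                s_f = _dp.dp_score(q, r, *args)
                s_r = _dp.dp_score((mol.length - q)[::-1], r, *args)
                if max(s_f, s_r) >= params.min_anchor_score:
                    n_hit += 1
            if member_idx and n_hit / len(member_idx) >= redundant_frac:
                redundant = True
                break
        if redundant:
            dropped.append(e.cmap.id)
        else:
            kept.append(e)
    return kept, dropped


def assemble(
    dataset: BnxDataset,
    params: AssemblyParams = AssemblyParams(),
) -> Tuple[CmapDataset, AssemblyReport]:
    """Cluster, anchor and consensus-call a molecule dataset into genome maps."""
    report = AssemblyReport(n_input=len(dataset.molecules))
    mols: List[Molecule] = []
    for m in dataset.molecules:
        if m.length < params.min_mol_len:
            report.n_filtered_short += 1
        elif m.n_labels < 2:
            report.n_filtered_degenerate += 1
            report.discarded.append(m.id)
        else:
            mols.append(m)
    header = {"Assembler": "nanomap", "Linkage": params.linkage,
              "ClusterCut": f"{params.cluster_cut:g}",
              "Bandwidth": f"{params.kde_bandwidth:g}"}
    if not mols:
        return CmapDataset(maps=[], header=header), report

    label_lists = [np.asarray(m.labels, float) for m in mols]
    pairs = candidate_pairs(label_lists, params)
    condensed, edges = pairwise_distances(mols, params, pairs=pairs)
    clusters, discarded_idx = cluster_molecules(condensed, params)
    report.discarded.extend(mols[i].id for i in discarded_idx)

    edge_lookup: Dict[int, List[Tuple[int, int, float, float]]] = defaultdict(list)
    cluster_of: Dict[int, int] = {}
    for k, members in enumerate(clusters):
        for i in members:
            cluster_of[i] = k
    for i, j, s, d in edges:
        if cluster_of.get(i, -1) == cluster_of.get(j, -2):
            edge_lookup[cluster_of[i]].append((i, j, s, d))

    entries: List[_MapEntry] = []
    for k, members in enumerate(clusters):
        # a cluster may anchor into several connected layouts when a thin
        # spot breaks the chain: re-anchor the set-aside molecules until too
        # few remain, so each connected piece becomes its own map
        queue = list(members)
        cluster_edges = edge_lookup[k]
        while len(queue) >= params.min_molecules_per_map:
            local_index = {g: l for l, g in enumerate(queue)}
            local_mols = [mols[g] for g in queue]
            local_edges = [(local_index[i], local_index[j], s, d)
                           for i, j, s, d in cluster_edges
                           if i in local_index and j in local_index]
            placements, set_aside = anchor_cluster(local_mols, params, edges=local_edges)
            if len(placements) < params.min_molecules_per_map:
                report.discarded.extend(local_mols[p.index].id for p in placements)
                queue = [queue[i] for i in set_aside]
                break
            placements = _global_offset_adjust(local_mols, placements, local_edges, params)
            for _ in range(params.refine_iterations):
                placements = _refine_placements(local_mols, placements, params)
                placements = _global_offset_adjust(local_mols, placements, local_edges, params)
            cmap = call_consensus(local_mols, placements, params,
                                  map_id=f"raw_{len(entries) + 1}")
            if cmap.n_labels > 0:
                entries.append(_MapEntry(mols=local_mols, placements=placements,
                                         cmap=cmap))
            if len(set_aside) >= len(queue):
                break  # no progress
            queue = [queue[i] for i in set_aside]
        report.set_aside.extend(mols[g].id for g in queue)

    # near-complete duplicates are purged before merging so junk cannot
    # graft itself onto a good map as a spurious extension; genuine
    # overlap-extenders (only part of their molecules shared) survive to
    # be merged, and a stricter purge mops up afterwards
    entries, dropped = _purge_redundant(entries, params, redundant_frac=0.8)
    entries = _merge_overlapping_maps(entries, params)
    entries, dropped2 = _purge_redundant(entries, params, redundant_frac=0.6)
    report.redundant = dropped + dropped2
    # renumber deterministically, longest first
    maps: List[ConsensusMap] = []
    for idx, e in enumerate(sorted(entries, key=lambda e: (-e.cmap.length, e.cmap.id)),
                            start=1):
        e.cmap.id = f"map_{idx}"
        maps.append(e.cmap)
        report.cluster_sizes.append(len(e.placements))
        report.placements[e.cmap.id] = e.placements
    return CmapDataset(maps=maps, header=header), report


# ---------------------------------------------------------------------------
# Depth titration
# ---------------------------------------------------------------------------


@dataclass
class DepthTitrationResult:
    """Assembly quality (N50, map count) versus molecule depth."""

    depths: List[float]
    n50s: List[float]
    map_counts: List[int]
    seeds: List[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "n50": self.n50s,
            "map_count": self.map_counts,
            "seed": self.seeds,
        })

    def median_by_depth(self) -> pd.DataFrame:
        return self.to_frame().groupby("depth").agg(
            n50=("n50", "median"), map_count=("map_count", "median")).reset_index()


def depth_titration(
    dataset: BnxDataset,
    genome_size: float,
    depths: Sequence[float],
    replicates: int = 1,
    seed: int = 0,
    params: AssemblyParams = AssemblyParams(),
) -> DepthTitrationResult:
    """Re-assemble subsampled molecule sets of increasing coverage.

    For each depth, molecules are drawn without replacement (total length
    matched to ``depth * genome_size``) and assembled with identical
    parameters; N50 and map count are recorded per replicate.
    """
    total = dataset.total_length()
    for d in depths:
        if d * genome_size > total * (1 + 1e-9):
            raise ValidationError(
                f"requested depth {d} exceeds dataset depth {total / genome_size:.1f}")
    base = np.random.default_rng(seed)
    rep_seeds = base.integers(0, 2 ** 31 - 1, size=replicates)
    out = DepthTitrationResult(depths=[], n50s=[], map_counts=[], seeds=[])
    # nested design: within a replicate the subsets are prefixes of one
    # random molecule order, so a deeper subset is a strict superset of a
    # shallower one and depth effects are not confounded with resampling
    for _rep in range(replicates):
        s = int(rep_seeds[_rep])
        rng = np.random.default_rng(s)
        perm = rng.permutation(len(dataset.molecules))
        cum = np.cumsum([dataset.molecules[i].length for i in perm])
        for d in depths:
            target = d * genome_size
            n_take = int(np.searchsorted(cum, target)) + 1
            chosen = sorted(int(i) for i in perm[:n_take])
            sub = BnxDataset(molecules=[dataset.molecules[i] for i in chosen],
                             header=dict(dataset.header))
            maps, _rep_info = assemble(sub, params)
            lengths = maps.lengths()
            out.depths.append(float(d))
            out.n50s.append(float(n50(lengths)) if len(lengths) else 0.0)
            out.map_counts.append(len(maps))
            out.seeds.append(s)
    return out
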