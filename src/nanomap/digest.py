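"""In-silico nicking-endonuclease digestion and enzyme selection.

A nicking endonuclease cuts one strand at its recognition motif; after nick
translation the fluorescent label appears on the molecule regardless of
which strand carried the site, so both orientations of the motif are
scanned and pooled. Sites closer than the optical resolution (~500 bp)
cannot be distinguished and are merged into a single label; this is why the
label density of an enzyme is always at or below its nick density.

Coordinates are 0-based positions of the leftmost base of a motif
occurrence on the forward strand. Motif windows containing N never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import CmapDataset, DigestParams, LabelMap, SequenceRecord, ValidationError

__all__ = [
    "reverse_complement",
    "find_motif_sites",
    "find_motif_sites_naive",
    "nick_density",
    "apply_resolution",
    "digest_record",
    "digest_sequences",
    "DigestResult",
    "EnzymeReportRow",
    "enzyme_report",
    "fluctuation_band",
    "DEFAULT_ENZYMES",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# The only recognition sequence shipped by default; further enzymes are
# supplied by the caller (catalog name -> motif).
DEFAULT_ENZYMES: Dict[str, str] = {"Nt.BspQ1": "GCTCTTC"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValidationError(f"motif {motif!r} must be a non-empty string over A/C/G/T")
    return motif


def _scan(sequence: str, pattern: str) -> List[int]:
    """All occurrence start positions of ``pattern`` in ``sequence``."""
    hits: List[int] = []
    start = 0
    while True:
        idx = sequence.find(pattern, start)
        if idx < 0:
            return hits
        hits.append(idx)
        start = idx + 1  # overlapping occurrences allowed


def find_motif_sites(seq: SequenceRecord, motif: str) -> np.ndarray:
    """Double-strand motif scan.

    Returns the sorted, deduplicated union of forward-strand matches and
    reverse-complement-motif matches, each reported as the 0-based position
    of the occurrence's leftmost base on the forward strand.
    """
    motif = _check_motif(motif)
    sequence = seq.sequence
    fwd = _scan(sequence, motif)
    rc = reverse_complement(motif)
    if rc == motif:
        rev: List[int] = []
    else:
        rev = _scan(sequence, rc)
    sites = np.unique(np.array(fwd + rev, dtype=np.int64))
    return sites


def find_motif_sites_naive(seq: SequenceRecord, motif: str) -> np.ndarray:
    """Brute-force O(n*m) double-strand sliding-window scan (test oracle)."""
    motif = _check_motif(motif)
    rc = reverse_complement(motif)
    m = len(motif)
    s = seq.sequence
    out = []
    for i in range(len(s) - m + 1):
        window = s[i:i + m]
        if window == motif or window == rc:
            out.append(i)
    return np.array(sorted(set(out)), dtype=np.int64)


def nick_density(n_sites: int, length_bp: float, window: float = 100_000.0) -> float:
    """Sites per ``window`` bp (default: per 100 kb)."""
    if length_bp <= 0:
        raise ValidationError("length_bp must be positive")
    return n_sites / length_bp * window


def apply_resolution(positions: Sequence[float], resolution_bp: float) -> np.ndarray:
    """Merge nicking sites closer than the optical resolution.

    Maximal chains of consecutive positions whose successive gaps are all
    strictly below ``resolution_bp`` collapse to a single label at the
    midpoint of the chain's extremes. Output gaps are therefore all
    >= ``resolution_bp`` and the operation is idempotent.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) == 0:
        return pos.copy()
    if np.any(np.diff(pos) < 0):
        raise ValidationError("positions must be ascending")
    if resolution_bp <= 0:
        return pos.copy()
    out: List[float] = []
    chain_start = pos[0]
    prev = pos[0]
    for p in pos[1:]:
        if p - prev < resolution_bp:
            prev = p
        else:
            out.append(0.5 * (chain_start + prev))
            chain_start = prev = p
    out.append(0.5 * (chain_start + prev))
    return np.array(out, dtype=float)


def digest_record(record: SequenceRecord, params: DigestParams) -> Tuple[LabelMap, int]:
    """Digest one sequence; returns (label map, raw nick-site count)."""
    sites = find_motif_sites(record, params.motif)
    labels = apply_resolution(sites.astype(float), params.resolution_bp)
    return (
        LabelMap(id=record.id, length=float(record.length), labels=labels, source="digest"),
        len(sites),
    )


@dataclass
class DigestResult:
    """Digest of a sequence collection with per-record and pooled densities.

    Aggregate densities are pooled counts over pooled length (not the mean
    of per-record densities), so they are invariant to how the genome is
    split into records.
    """

    maps: CmapDataset
    nick_counts: List[int]
    per_record_nick_density: List[float]
    per_record_label_density: List[float]
    nick_density: Optional[float]
    label_density: Optional[float]


def digest_sequences(records: Sequence[SequenceRecord], params: DigestParams) -> DigestResult:
    maps: List[LabelMap] = []
    nick_counts: List[int] = []
    nick_d: List[float] = []
    label_d: List[float] = []
    for rec in records:
        lm, n_sites = digest_record(rec, params)
        maps.append(lm)
        nick_counts.append(n_sites)
        nick_d.append(nick_density(n_sites, rec.length, params.density_window))
        label_d.append(nick_density(lm.n_labels, rec.length, params.density_window))
    total_len = float(sum(r.length for r in records))
    agg_nick = agg_label = None
    if total_len > 0:
        agg_nick = nick_density(sum(nick_counts), total_len, params.density_window)
        agg_label = nick_density(sum(m.n_labels for m in maps), total_len, params.density_window)
    header = {"Motif": params.motif, "Resolution": f"{params.resolution_bp:g}"}
    return DigestResult(
        maps=CmapDataset(maps=maps, header=header),
        nick_counts=nick_counts,
        per_record_nick_density=nick_d,
        per_record_label_density=label_d,
        nick_density=agg_nick,
        label_density=agg_label,
    )


@dataclass(frozen=True)
class EnzymeReportRow:
    """One enzyme-candidate row of the selection report."""

    enzyme: str
    motif: str
    nick_density: float
    label_density: float


def enzyme_report(
    records: Sequence[SequenceRecord],
    catalog: Optional[Dict[str, str]] = None,
    target_density: float = 10.0,
    resolution_bp: float = 500.0,
) -> Tuple[List[EnzymeReportRow], str]:
    """Evaluate candidate nicking enzymes on a genome.

    Returns the per-enzyme densities (in catalog order) and the name of the
    enzyme whose label density is closest to ``target_density`` (~10 per
    100 kb is the platform's optimum; ties go to the first candidate).
    """
    if catalog is None:
        catalog = DEFAULT_ENZYMES
    if not catalog:
        raise ValidationError("enzyme catalog is empty")
    rows: List[EnzymeReportRow] = []
    for name, motif in catalog.items():
        params = DigestParams(motif=motif, resolution_bp=resolution_bp)
        result = digest_sequences(records, params)
        rows.append(
            EnzymeReportRow(
                enzyme=name,
                motif=motif.upper(),
                nick_density=result.nick_density if result.nick_density is not None else 0.0,
                label_density=result.label_density if result.label_density is not None else 0.0,
            )
        )
    selected = min(rows, key=lambda r: abs(r.label_density - target_density)).enzyme
    return rows, selected


def fluctuation_band(density: float, frac: float = 0.15) -> Tuple[float, float]:
    """Expected whole-genome density band around a pilot estimate (+/- frac)."""
    if density < 0:
        raise ValidationError("density must be >= 0")
    if not (0.0 <= frac < 1.0):
        raise ValidationError("frac must be in [0, 1)")
    return density * (1.0 - frac), density * (1.0 + frac)
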