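"""Core domain containers for the optical-mapping pipeline.

The pipeline manipulates three kinds of label-position data:

* in-silico digests of genome sequences (``LabelMap`` with ``source="digest"``),
* observed (noisy) single molecules (``Molecule``), and
* assembled consensus genome maps (``ConsensusMap``).

All coordinates are base pairs on the object's own axis, 0-based, stored as
floats (optical positions are sub-base-pair after averaging). Label lists are
kept ascending; validators enforce this at construction of the dataset
containers rather than on every mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SequenceRecord",
    "LabelMap",
    "ConsensusMap",
    "Molecule",
    "BnxDataset",
    "CmapDataset",
    "DigestParams",
    "NoiseModel",
    "MoleculeLengthModel",
    "AssemblyParams",
    "AlignParams",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def _as_label_array(labels: Sequence[float]) -> np.ndarray:
    arr = np.asarray(labels, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("label positions must be one-dimensional")
    return arr


def _check_labels(labels: np.ndarray, length: float, owner: str) -> None:
    if len(labels) and (np.any(np.diff(labels) < 0)):
        raise ValidationError(f"{owner}: label positions must be sorted ascending")
    if len(labels) and (labels[0] < 0 or labels[-1] > length + 1e-6):
        raise ValidationError(f"{owner}: label positions must lie within [0, length]")


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"sequence record {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabelMap:
    """An ordered set of label positions on a sequence or map."""

    id: str
    length: float
    labels: np.ndarray
    source: str = "digest"  # {"digest", "simulation", "assembly"}

    def __post_init__(self) -> None:
        self.labels = _as_label_array(self.labels)
        if self.length <= 0:
            raise ValidationError(f"map {self.id!r}: length must be positive")
        _check_labels(self.labels, self.length, f"map {self.id!r}")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def values_equal(self, other: "LabelMap", tol: float = 0.05) -> bool:
        return (
            self.id == other.id
            and abs(self.length - other.length) <= tol
            and len(self.labels) == len(other.labels)
            and (len(self.labels) == 0 or np.allclose(self.labels, other.labels, atol=tol))
        )


@dataclass
class ConsensusMap(LabelMap):
    """An assembled consensus genome map with per-label molecule support."""

    source: str = "assembly"
    support: Optional[np.ndarray] = None
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.support is None:
            self.support = np.ones(len(self.labels), dtype=int)
        else:
            self.support = np.asarray(self.support, dtype=int)
        if len(self.support) != len(self.labels):
            raise ValidationError(f"map {self.id!r}: support and labels length mismatch")
        if len(self.support) and self.support.min() < 1:
            raise ValidationError(f"map {self.id!r}: per-label support must be >= 1")


@dataclass
class Molecule:
    """An observed labelled DNA molecule.

    ``truth`` is simulation metadata (absent for real data): the genomic
    interval the molecule was drawn from, its strand, the number of true
    labels in that interval, how many were dropped as false negatives, and
    for each observed label the tuple of true-label indices it derives from
    (empty tuple = pure false positive).
    """

    id: str
    length: float
    labels: np.ndarray
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.labels = _as_label_array(self.labels)
        if self.length <= 0:
            raise ValidationError(f"molecule {self.id!r}: length must be positive")
        _check_labels(self.labels, self.length, f"molecule {self.id!r}")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def as_label_map(self) -> LabelMap:
        return LabelMap(id=self.id, length=self.length, labels=self.labels.copy(), source="simulation")


def _check_unique_ids(ids: List[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class BnxDataset:
    """An ordered collection of molecules plus header metadata."""

    molecules: List[Molecule] = field(default_factory=list)
    header: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique_ids([m.id for m in self.molecules], "molecule")

    def __len__(self) -> int:
        return len(self.molecules)

    def total_length(self) -> float:
        return float(sum(m.length for m in self.molecules))

    def lengths(self) -> np.ndarray:
        return np.array([m.length for m in self.molecules], dtype=float)


@dataclass
class CmapDataset:
    """An ordered collection of label maps / consensus maps plus metadata."""

    maps: List[LabelMap] = field(default_factory=list)
    header: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique_ids([m.id for m in self.maps], "map")

    def __len__(self) -> int:
        return len(self.maps)

    def total_length(self) -> float:
        return float(sum(m.length for m in self.maps))

    def lengths(self) -> np.ndarray:
        return np.array([m.length for m in self.maps], dtype=float)


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestParams:
    """Nicking-endonuclease in-silico digestion parameters.

    ``resolution_bp`` is the optical labelling resolution: nicking sites
    closer than this cannot be resolved as separate fluorescent labels and
    are merged into one.
    """

    motif: str = "GCTCTTC"  # Nt.BspQ1 recognition site
    resolution_bp: float = 500.0
    density_window: float = 100_000.0  # densities are quoted per 100 kb

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValidationError("motif must be at least 4 bases")
        if set(self.motif.upper()) - set("ACGT"):
            raise ValidationError("motif must be over {A,C,G,T}")
        if self.resolution_bp < 0:
            raise ValidationError("resolution_bp must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Nanochannel measurement error model for simulated molecules.

    fp_rate          spurious labels per 100 kb of molecule length
    fn_prob          per-true-label probability of not being labelled
    sizing_sd_scale  s0 in sd(gap) = s0 * sqrt(gap), bp^0.5
    stretch_mean     mean per-molecule linear stretch (observed/true scale);
                     1.008 emulates an effective 504 bp/pixel at a 500 bp
                     nominal pixel scale
    stretch_sd       sd of the per-molecule stretch factor
    bpp              bp per camera pixel; observed positions are quantized
                     to this grid (0 disables quantization)
    resolution_bp    optical resolution; observed labels closer than this
                     merge into one
    """

    fp_rate: float = 1.5
    fn_prob: float = 0.15
    sizing_sd_scale: float = 5.0
    stretch_mean: float = 1.008
    stretch_sd: float = 0.01
    bpp: float = 500.0
    resolution_bp: float = 500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fn_prob <= 1.0):
            raise ValidationError("fn_prob must be in [0, 1]")
        for name in ("fp_rate", "sizing_sd_scale", "stretch_sd", "bpp", "resolution_bp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        return cls(fp_rate=0.0, fn_prob=0.0, sizing_sd_scale=0.0,
                   stretch_mean=1.0, stretch_sd=0.0, bpp=0.0)


@dataclass(frozen=True)
class MoleculeLengthModel:
    """Heavy-tailed molecule length law: log-normal truncated at ``min_len``.

    ``sigma`` is the log-sd; ``mu`` is calibrated at sampling time by
    root-finding so that the distribution's N50 equals ``target_n50``.
    """

    min_len: float = 100_000.0
    target_n50: float = 176_000.0
    sigma: float = 0.55

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValidationError("min_len must be positive")
        if self.target_n50 < self.min_len:
            raise ValidationError("target_n50 must be >= min_len")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for ordered-label dynamic-programming alignment.

    The FP/FN rates parameterize per-label skip penalties as negative log
    probabilities: skipping a reference label costs -ln(fn_penalty_prob);
    skipping a query label costs -ln(fp_penalty_rate * resolution_bp / 1e5),
    i.e. the log-probability of a false label in one resolution window.
    A matched pair earns ``match_bonus`` (default: the sum of both skip
    penalties, so matching always beats double-skipping) minus a Gaussian
    sizing term (dr - dq)^2 / (2 * s0^2 * max(dr, resolution_bp)).
    """

    fp_penalty_rate: float = 1.5
    fn_penalty_prob: float = 0.15
    sizing_sd_scale: float = 5.0
    min_query_sites: int = 7  # "more than 6" label filter
    min_score: float = 15.0
    resolution_bp: float = 500.0
    max_skip: int = 8
    match_bonus: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fn_penalty_prob < 1.0):
            raise ValidationError("fn_penalty_prob must be in (0, 1)")
        if self.fp_penalty_rate <= 0:
            raise ValidationError("fp_penalty_rate must be positive")
        if self.sizing_sd_scale < 0:
            raise ValidationError("sizing_sd_scale must be >= 0")
        if self.max_skip < 1:
            raise ValidationError("max_skip must be >= 1")

    @property
    def fn_penalty(self) -> float:
        return -math.log(self.fn_penalty_prob)

    @property
    def fp_penalty(self) -> float:
        p = self.fp_penalty_rate * self.resolution_bp / 100_000.0
        return -math.log(min(p, 0.999999))

    @property
    def bonus(self) -> float:
        if self.match_bonus is not None:
            return self.match_bonus
        return self.fp_penalty + self.fn_penalty


@dataclass(frozen=True)
class AssemblyParams:
    """Consensus genome-map assembly parameters."""

    min_mol_len: float = 100_000.0
    linkage: str = "single"  # {"single", "average", "complete"}
    cluster_cut: float = 0.5
    kde_bandwidth: float = 500.0
    min_peak_support_frac: float = 0.25
    min_molecules_per_map: int = 3
    resolution_bp: float = 500.0
    # overlap-candidate prefilter: gap k-mer fingerprints
    fingerprint_k: int = 3
    fingerprint_quantum: float = 500.0
    min_shared_fingerprints: int = 2
    max_candidates_per_mol: int = 80
    # anchoring
    min_anchor_score: float = 25.0
    min_anchor_pairs: int = 5
    max_scale_dev: float = 0.05  # reject placements with ||scale| - 1| beyond this
    orientation_margin: float = 4.0  # best orientation must beat the other by this
    placement_agree_tol: float = 20_000.0  # bp; multi-neighbour offset vote window
    max_place_checks: int = 12  # neighbours consulted per placement vote
    refine_iterations: int = 2
    consensus_grid: float = 100.0
    align: AlignParams = field(default_factory=lambda: AlignParams(max_skip=5))

    def __post_init__(self) -> None:
        if self.linkage not in ("single", "average", "complete"):
            raise ValidationError("linkage must be one of single/average/complete")
        if not (0.0 <= self.cluster_cut <= 1.0):
            raise ValidationError("cluster_cut must be in [0, 1]")
        if not (0.0 <= self.min_peak_support_frac <= 1.0):
            raise ValidationError("min_peak_support_frac must be in [0, 1]")
        if self.min_molecules_per_map < 1:
            raise ValidationError("min_molecules_per_map must be >= 1")


def with_params(obj, **kwargs):
    """Return a copy of a frozen parameter block with fields replaced."""
    return replace(obj, **kwargs)
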