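"""Descriptive statistics for molecules, maps and digests.

Conventions pinned here: N50 is the smallest element length L such that
elements of length >= L sum to at least half the total (descending sort,
cumulate); pooled densities are total counts over total length (never the
mean of per-item densities); histogram bins are right-open [left, right).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import BnxDataset, CmapDataset, Molecule, ValidationError

__all__ = [
    "n50",
    "summary_table",
    "length_histogram",
    "label_density_stats",
    "depth_threshold_table",
    "coverage",
]


def n50(lengths: Sequence[float]) -> float:
    """Smallest length whose at-least-as-long elements cover half the total."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValidationError("n50 of an empty length list is undefined")
    if np.any(arr <= 0):
        raise ValidationError("lengths must be positive")
    srt = np.sort(arr)[::-1]
    cum = np.cumsum(srt)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(srt[idx])


def _lengths_of(dataset: Union[BnxDataset, CmapDataset, Sequence[float]]) -> np.ndarray:
    if isinstance(dataset, (BnxDataset, CmapDataset)):
        return dataset.lengths()
    return np.asarray(dataset, dtype=float)


def summary_table(named_datasets: Dict[str, Union[BnxDataset, CmapDataset, Sequence[float]]]
                  ) -> pd.DataFrame:
    """Number / total length / N50 / min / max per named dataset."""
    rows = []
    for label, ds in named_datasets.items():
        lengths = _lengths_of(ds)
        if lengths.size == 0:
            rows.append({"label": label, "number": 0, "total_length": 0.0,
                         "n50": np.nan, "min": np.nan, "max": np.nan})
        else:
            rows.append({
                "label": label,
                "number": int(lengths.size),
                "total_length": float(lengths.sum()),
                "n50": n50(lengths),
                "min": float(lengths.min()),
                "max": float(lengths.max()),
            })
    return pd.DataFrame(rows, columns=["label", "number", "total_length", "n50", "min", "max"])


def length_histogram(
    lengths: Sequence[float],
    bin_width: float = 50_000.0,
    tail_accumulate_at: Optional[float] = None,
) -> pd.DataFrame:
    """Counts and total length per right-open length bin.

    Values at or above ``tail_accumulate_at`` are accumulated into a final
    open-ended bin (the "everything longer than X" bar).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    arr = np.asarray(lengths, dtype=float)
    rows = []
    if arr.size:
        top = float(arr.max())
        cap = tail_accumulate_at if tail_accumulate_at is not None else np.inf
        n_closed = int(min(top, cap if np.isfinite(cap) else top) // bin_width) + 1
        if tail_accumulate_at is not None:
            n_closed = int(np.ceil(tail_accumulate_at / bin_width))
        for b in range(n_closed):
            lo, hi = b * bin_width, (b + 1) * bin_width
            sel = (arr >= lo) & (arr < hi)
            rows.append({"bin_left": lo, "bin_right": hi,
                         "count": int(sel.sum()), "total_length": float(arr[sel].sum())})
        if tail_accumulate_at is not None:
            sel = arr >= tail_accumulate_at
            rows.append({"bin_left": float(tail_accumulate_at), "bin_right": np.inf,
                         "count": int(sel.sum()), "total_length": float(arr[sel].sum())})
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "count", "total_length"])


def label_density_stats(
    molecules: Union[BnxDataset, Sequence[Molecule]],
    length_bin_width: float = 50_000.0,
    window: float = 100_000.0,
) -> Dict[str, object]:
    """Per-molecule label densities plus pooled overall density.

    The overall density is total labels over total length (pooled), which
    differs from the mean of per-molecule densities when lengths vary; both
    are reported. Per-length-bin quartiles give boxplot-ready data.
    """
    mols = molecules.molecules if isinstance(molecules, BnxDataset) else list(molecules)
    lengths = np.array([m.length for m in mols], dtype=float)
    counts = np.array([m.n_labels for m in mols], dtype=float)
    if np.any(lengths <= 0):
        raise ValidationError("molecule lengths must be positive")
    densities = counts / lengths * window
    overall = float(counts.sum() / lengths.sum() * window) if lengths.size else np.nan
    per_bin = []
    if lengths.size:
        bins = (lengths // length_bin_width).astype(int)
        for b in sorted(set(bins)):
            sel = bins == b
            qs = np.percentile(densities[sel], [25, 50, 75])
            per_bin.append({
                "bin_left": b * length_bin_width,
                "bin_right": (b + 1) * length_bin_width,
                "count": int(sel.sum()),
                "q1": float(qs[0]), "median": float(qs[1]), "q3": float(qs[2]),
            })
    return {
        "densities": densities,
        "overall": overall,
        "mean_per_molecule": float(densities.mean()) if lengths.size else np.nan,
        "per_length_bin": pd.DataFrame(per_bin,
                                       columns=["bin_left", "bin_right", "count",
                                                "q1", "median", "q3"]),
    }


def depth_threshold_table(
    molecules: Union[BnxDataset, Sequence[Molecule]],
    thresholds: Sequence[float],
    genome_size: float,
) -> pd.DataFrame:
    """Molecule count and mean genome depth per minimum-length threshold."""
    if genome_size <= 0:
        raise ValidationError("genome_size must be positive")
    mols = molecules.molecules if isinstance(molecules, BnxDataset) else list(molecules)
    lengths = np.array([m.length for m in mols], dtype=float)
    rows = []
    for t in thresholds:
        sel = lengths >= t
        rows.append({
            "threshold": float(t),
            "n_molecules": int(sel.sum()),
            "depth": float(lengths[sel].sum() / genome_size),
        })
    return pd.DataFrame(rows, columns=["threshold", "n_molecules", "depth"])


def coverage(total_molecule_length: float, genome_size: float) -> float:
    """Fold coverage of the genome by the molecule set."""
    if genome_size <= 0:
        raise ValidationError("genome_size must be positive")
    return total_molecule_length / genome_size
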