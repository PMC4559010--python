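"""Synthetic genomes and nanochannel molecule simulation.

The generator emulates the measured properties of a real nanochannel
optical-mapping run on a fish-sized genome: molecules at least 100 kb long
with an N50 around 176 kb, ~10-11 labels per 100 kb, ~1.5 false labels per
100 kb, a 15 % per-label miss probability, square-root sizing noise on
inter-label gaps, a per-molecule linear stretch (504 bp effective pixel
scale at a 500 bp nominal), and a 500 bp labelling resolution.

Every stage is deterministic given a seed; per-molecule noise streams are
derived from (seed, molecule index) so that datasets are reproducible and
molecules independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .digest import apply_resolution, digest_record, find_motif_sites, reverse_complement
from .models import (
    BnxDataset,
    DigestParams,
    Molecule,
    MoleculeLengthModel,
    NoiseModel,
    SequenceRecord,
    ValidationError,
)

__all__ = [
    "simulate_genome",
    "motif_probability",
    "sample_molecule_intervals",
    "corrupt_molecule",
    "generate_dataset",
    "validate_rates",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def motif_probability(motif: str, gc: float) -> float:
    """Per-position probability of a motif under i.i.d. bases at given GC."""
    p = 1.0
    for base in motif.upper():
        p *= gc / 2.0 if base in "GC" else (1.0 - gc) / 2.0
    return p


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> bytearray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=probs)
    return bytearray(_BASES[idx].tobytes())


def simulate_genome(
    length: int,
    gc: float = 0.41,
    target_label_density: float = 11.0,
    seed: Union[int, np.random.Generator] = 0,
    motif: str = "GCTCTTC",
    resolution_bp: float = 500.0,
    target_nick_density: Optional[float] = None,
    record_id: str = "chr_sim",
) -> SequenceRecord:
    """Random genome with motif copies planted to hit a target label density.

    Background bases are i.i.d. at the given GC content; on top of the
    background occurrences of the motif, single motif copies (and, when
    ``target_nick_density`` exceeds what singles can deliver, close pairs
    that merge into one label) are planted at Poisson spacings, with rates
    tuned analytically so that the post-resolution label density of the
    digest is approximately ``target_label_density`` per 100 kb. A rescan
    after planting warns if the realized density is far from the target.
    """
    if length < 10_000:
        raise ValidationError("genome length must be at least 10 kb")
    if not (0.0 < gc < 1.0):
        raise ValidationError("gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    seq = _random_bases(rng, length, gc)

    # expected background rates (per bp): both strands of a non-palindromic motif
    p = motif_probability(motif, gc)
    n_strands = 1 if reverse_complement(motif) == motif.upper() else 2
    bg_nick = n_strands * p
    # a site starts a label chain iff no site within `resolution_bp` upstream
    bg_label = bg_nick * math.exp(-bg_nick * resolution_bp)

    per_bp_target = target_label_density / 100_000.0
    lam_single = max(0.0, per_bp_target - bg_label)
    lam_pair = 0.0
    if target_nick_density is not None:
        nick_target = target_nick_density / 100_000.0
        lam_pair = max(0.0, (nick_target - bg_nick) - lam_single)
        lam_single = max(0.0, lam_single - lam_pair)
    if per_bp_target < bg_label * 0.95:
        warnings.warn(
            f"target label density {target_label_density:.2f}/100kb is below the "
            f"expected background {bg_label * 1e5:.2f}/100kb; planting nothing",
            stacklevel=2,
        )

    m = len(motif)
    fwd = motif.upper().encode()
    rev = reverse_complement(motif).encode()

    def plant(pos: int) -> None:
        copy = fwd if rng.random() < 0.5 else rev
        seq[pos:pos + m] = copy

    n_single = rng.poisson(lam_single * length)
    n_pair = rng.poisson(lam_pair * length)
    singles = np.sort(rng.integers(0, length - m, size=n_single))
    for pos in singles:
        plant(int(pos))
    pair_starts = np.sort(rng.integers(0, length - m - int(resolution_bp), size=n_pair))
    for pos in pair_starts:
        plant(int(pos))
        offset = int(rng.integers(m + 5, int(resolution_bp) - 10))
        plant(int(pos) + offset)

    record = SequenceRecord(id=record_id, sequence=seq.decode())
    realized = len(apply_resolution(
        find_motif_sites(record, motif).astype(float), resolution_bp)) / length * 1e5
    if target_label_density > 0 and abs(realized - target_label_density) > max(
            2.0, 0.3 * target_label_density):
        warnings.warn(
            f"realized label density {realized:.2f}/100kb differs from target "
            f"{target_label_density:.2f}/100kb",
            stacklevel=2,
        )
    return record


# ---------------------------------------------------------------------------
# Molecule length model
# ---------------------------------------------------------------------------


def _upper_mean(z: float, sigma: float, log_a: float) -> float:
    """E[X 1(X >= a)] / exp(mu + sigma^2/2) for lognormal, with z = mu + sigma^2."""
    return norm.cdf((z - log_a) / sigma)


@lru_cache(maxsize=None)
def _calibrate_mu(min_len: float, target_n50: float, sigma: float) -> float:
    """Choose lognormal mu so the truncated law's N50 equals target_n50.

    The N50 of the distribution is the length t with
    E[X 1(X>=t)] = 0.5 * E[X 1(X>=min_len)]; both expectations have the
    closed form exp(mu + s^2/2) * Phi((mu + s^2 - ln a) / s).
    """
    log_m = math.log(min_len)
    log_t = math.log(target_n50)

    def f(z: float) -> float:
        return _upper_mean(z, sigma, log_t) / _upper_mean(z, sigma, log_m) - 0.5

    lo, hi = log_m - 8 * sigma, log_t + 8 * sigma
    # expand until bracketing (f is increasing in z)
    while f(lo) > 0:
        lo -= 2 * sigma
    while f(hi) < 0:
        hi += 2 * sigma
    z = brentq(f, lo, hi, xtol=1e-10)
    return z - sigma ** 2


def _draw_lengths(rng: np.random.Generator, n: int, model: MoleculeLengthModel,
                  cap: float) -> np.ndarray:
    """Draw n molecule lengths from the truncated lognormal law."""
    mu = _calibrate_mu(model.min_len, model.target_n50, model.sigma)
    out = np.empty(0)
    while len(out) < n:
        batch = rng.lognormal(mean=mu, sigma=model.sigma, size=max(2 * n, 64))
        batch = batch[batch >= model.min_len]
        out = np.concatenate([out, batch])
    lengths = out[:n]
    return np.minimum(lengths, cap)


def sample_molecule_intervals(
    genome_length: float,
    depth: float,
    model: MoleculeLengthModel = MoleculeLengthModel(),
    seed: Union[int, np.random.Generator] = 0,
) -> List[Tuple[float, float]]:
    """Uniformly placed genomic intervals totalling ``depth`` x genome length.

    Lengths follow the truncated length law (capped at the genome length);
    sampling stops as soon as the accumulated length reaches the target.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if genome_length < model.min_len:
        raise ValidationError("genome shorter than the minimum molecule length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = depth * genome_length
    intervals: List[Tuple[float, float]] = []
    total = 0.0
    while total < target:
        n_guess = max(16, int((target - total) / model.target_n50 * 1.5))
        lengths = _draw_lengths(rng, n_guess, model, genome_length)
        starts = rng.uniform(0.0, genome_length - lengths)
        for L, s in zip(lengths, starts):
            intervals.append((float(s), float(s + L)))
            total += L
            if total >= target:
                break
    return intervals


# ---------------------------------------------------------------------------
# Measurement error model
# ---------------------------------------------------------------------------


def corrupt_molecule(
    true_labels: Sequence[float],
    interval_length: float,
    noise: NoiseModel = NoiseModel(),
    seed: Union[int, np.random.Generator] = 0,
    mol_id: str = "mol",
    truth_meta: Optional[dict] = None,
) -> Molecule:
    """Apply the measurement error model to a molecule's true label track.

    Pipeline order: (1) drop each true label with probability ``fn_prob``;
    (2) add Poisson false labels uniformly along the molecule; (3) perturb
    every inter-label gap (including the two flanks) with Gaussian noise of
    sd ``s0 * sqrt(gap)`` and re-accumulate; (4) apply a per-molecule linear
    stretch; (5) quantize to the pixel grid; (6) merge labels closer than
    the resolution. Truth correspondence (which observed label derives from
    which true labels, if any) is recorded through every stage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true = np.asarray(true_labels, dtype=float)
    if len(true) and (np.any(np.diff(true) < 0) or true[0] < 0 or true[-1] > interval_length + 1e-6):
        raise ValidationError("true labels must be ascending within [0, interval_length]")
    n_true = len(true)

    # (1) false negatives
    keep = rng.random(n_true) >= noise.fn_prob
    positions = true[keep]
    origins: List[Tuple[int, ...]] = [(int(i),) for i in np.flatnonzero(keep)]

    # (2) false positives
    n_fp = rng.poisson(noise.fp_rate * interval_length / 100_000.0)
    if n_fp:
        fp_pos = rng.uniform(0.0, interval_length, size=n_fp)
        positions = np.concatenate([positions, fp_pos])
        origins = origins + [()] * n_fp
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        origins = [origins[k] for k in order]

    length = float(interval_length)

    # (3) sizing noise on gaps, re-accumulated
    if noise.sizing_sd_scale > 0:
        bounds = np.concatenate([[0.0], positions, [length]])
        gaps = np.diff(bounds)
        noisy = gaps + rng.normal(0.0, noise.sizing_sd_scale * np.sqrt(np.maximum(gaps, 1.0)))
        noisy = np.maximum(noisy, 1.0)
        acc = np.cumsum(noisy)
        positions = acc[:-1].copy()
        length = float(acc[-1])

    # (4) per-molecule stretch
    stretch = noise.stretch_mean + (rng.normal(0.0, noise.stretch_sd) if noise.stretch_sd > 0 else 0.0)
    stretch = max(stretch, 0.5)
    if stretch != 1.0:
        positions = positions * stretch
        length *= stretch

    # (5) pixel quantization
    if noise.bpp > 0:
        positions = np.round(positions / noise.bpp) * noise.bpp
        length = max(float(np.round(length / noise.bpp) * noise.bpp),
                     float(positions[-1]) if len(positions) else noise.bpp)

    # (6) resolution merge, pooling truth origins
    if len(positions) and noise.resolution_bp > 0:
        merged_pos: List[float] = []
        merged_org: List[Tuple[int, ...]] = []
        chain_start = positions[0]
        prev = positions[0]
        chain: Tuple[int, ...] = origins[0]
        for pos, org in zip(positions[1:], origins[1:]):
            if pos - prev < noise.resolution_bp:
                prev = pos
                chain = chain + org
            else:
                merged_pos.append(0.5 * (chain_start + prev))
                merged_org.append(chain)
                chain_start = prev = pos
                chain = org
        merged_pos.append(0.5 * (chain_start + prev))
        merged_org.append(chain)
        positions = np.array(merged_pos)
        origins = merged_org

    positions = np.clip(positions, 0.0, length)

    truth = {
        "n_true": int(n_true),
        "n_dropped": int(n_true - keep.sum()),
        "label_origins": origins,
    }
    if truth_meta:
        truth.update(truth_meta)
    return Molecule(id=mol_id, length=length, labels=positions, truth=truth)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    genome: SequenceRecord,
    digest_params: DigestParams = DigestParams(),
    depth: float = 100.0,
    length_model: MoleculeLengthModel = MoleculeLengthModel(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> Tuple[BnxDataset, pd.DataFrame]:
    """Simulate a molecule dataset from a genome; returns (dataset, truth table).

    The genome is digested in silico (post-resolution labels are the truth
    track molecules observe); intervals are sampled to the requested depth;
    each molecule is read off either strand with probability 1/2 and passed
    through the error model. The truth table maps every molecule to its
    genomic interval and label counts.
    """
    genome_map, _ = digest_record(genome, digest_params)
    sites = genome_map.labels
    rng = np.random.default_rng(seed)
    intervals = sample_molecule_intervals(genome.length, depth, length_model, rng)

    molecules: List[Molecule] = []
    rows = []
    n_rejected = 0
    for i, (start, end) in enumerate(intervals):
        sub_rng = np.random.default_rng([seed & 0x7FFFFFFF, i])
        lo = np.searchsorted(sites, start, side="left")
        hi = np.searchsorted(sites, end, side="right")
        seg = sites[lo:hi]
        strand = "+" if sub_rng.random() < 0.5 else "-"
        if strand == "+":
            local = seg - start
        else:
            local = (end - seg)[::-1]
        mol_id = f"mol_{i + 1:06d}"
        mol = corrupt_molecule(
            local, end - start, noise, sub_rng, mol_id=mol_id,
            truth_meta={"genome_id": genome.id, "start": float(start),
                        "end": float(end), "strand": strand},
        )
        if mol.length < length_model.min_len:
            # the platform's validity filter applies to the *observed* length
            n_rejected += 1
            continue
        molecules.append(mol)
        rows.append({
            "molecule_id": mol_id,
            "start": float(start),
            "end": float(end),
            "strand": strand,
            "observed_length": mol.length,
            "n_true": mol.truth["n_true"],
            "n_dropped": mol.truth["n_dropped"],
            "n_fp": sum(1 for o in mol.truth["label_origins"] if len(o) == 0),
            "n_observed": mol.n_labels,
        })
    header = {
        "Genome": genome.id,
        "Depth": f"{depth:g}",
        "BPP": f"{noise.bpp:g}",
        "MinMoleculeLength": f"{length_model.min_len:g}",
        "Seed": str(seed),
    }
    return BnxDataset(molecules=molecules, header=header), pd.DataFrame(rows)


def validate_rates(dataset: BnxDataset,
                   truth: Optional[pd.DataFrame] = None) -> Tuple[float, float]:
    """Estimate (fp per 100 kb, fn fraction) from simulation truth metadata.

    fp_hat counts observed labels with no true-label origin over the total
    molecule length; fn_hat counts dropped true labels over all true labels.
    """
    total_len = 0.0
    n_fp = 0
    n_true = 0
    n_dropped = 0
    for mol in dataset.molecules:
        if mol.truth is None or "label_origins" not in mol.truth:
            raise ValidationError(f"molecule {mol.id!r} has no simulation truth")
        total_len += mol.length
        n_fp += sum(1 for o in mol.truth["label_origins"] if len(o) == 0)
        n_true += mol.truth["n_true"]
        n_dropped += mol.truth["n_dropped"]
    if total_len == 0:
        raise ValidationError("empty dataset")
    fp_hat = n_fp / total_len * 100_000.0
    fn_hat = n_dropped / n_true if n_true else 0.0
    return fp_hat, fn_hat
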