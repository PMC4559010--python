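"""Readers and writers for the text formats the pipeline touches.

FASTA is handled through Biopython. BNX (molecule-level) and CMAP
(map-level) are emitted in a minimal, documented dialect compatible in
spirit with BNX v1.2 / CMAP v0.1 column order:

BNX::

    # BNX File Version:\t1.2-min
    # <key>\t<value>                      (free-form header metadata)
    0\t<molecule id>\t<length>
    1\t<pos>\t<pos>\t...                  (label positions, may be empty)

CMAP: one row per label site plus a terminal channel-0 row at the map
length (vendor convention), columns::

    #h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\tCoverage

Positions are written in bp with one decimal place; site ids are 1-based.
Writers are deterministic byte-for-byte; readers validate sortedness,
bounds and id uniqueness. Unknown header keys round-trip verbatim.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Tuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    BnxDataset,
    CmapDataset,
    ConsensusMap,
    LabelMap,
    Molecule,
    SequenceRecord,
    ValidationError,
)

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_bnx",
    "write_bnx",
    "bnx_roundtrip",
    "read_cmap",
    "write_cmap",
    "cmap_roundtrip",
]

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: Union[str, os.PathLike], on_invalid: str = "error") -> List[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased. Characters outside {A,C,G,T,N} raise a
    :class:`FormatError` naming the record, or are mapped to ``N`` when
    ``on_invalid="mask"``.
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError("on_invalid must be 'error' or 'mask'")
    records: List[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            if on_invalid == "error":
                raise FormatError(
                    f"record {rec.id!r}: invalid characters {sorted(bad)} (use on_invalid='mask')"
                )
            table = str.maketrans({c: "N" for c in bad})
            seq = seq.translate(table)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, os.PathLike],
                width: int = 80) -> None:
    seqio_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)


# ---------------------------------------------------------------------------
# BNX
# ---------------------------------------------------------------------------

_BNX_VERSION_KEY = "BNX File Version"
_CMAP_VERSION_KEY = "CMAP File Version"


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def write_bnx(dataset: BnxDataset, path: Union[str, os.PathLike]) -> None:
    """Write molecules in the minimal BNX dialect (deterministic bytes)."""
    lines: List[str] = [f"# {_BNX_VERSION_KEY}:\t1.2-min"]
    for key, value in dataset.header.items():
        if key == _BNX_VERSION_KEY:
            continue
        lines.append(f"# {key}:\t{value}")
    for mol in dataset.molecules:
        labels = np.asarray(mol.labels, dtype=float)
        if len(labels) and np.any(np.diff(labels) < 0):
            raise ValidationError(f"molecule {mol.id!r}: unsorted labels on write")
        if len(labels) and (labels[0] < 0 or labels[-1] > mol.length + 0.05):
            raise ValidationError(f"molecule {mol.id!r}: labels outside [0, length]")
        lines.append(f"0\t{mol.id}\t{_fmt(mol.length)}")
        lines.append("1" + "".join("\t" + _fmt(p) for p in labels))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bnx(path: Union[str, os.PathLike]) -> BnxDataset:
    header: Dict[str, str] = {}
    molecules: List[Molecule] = []
    pending: Tuple[str, float] = None  # (id, length) awaiting its label row
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header[key.strip()] = value.strip().lstrip("\t").strip()
                continue
            fields = line.split("\t")
            if fields[0] == "0":
                if pending is not None:
                    raise FormatError(f"line {lineno}: molecule {pending[0]!r} missing label row")
                if len(fields) != 3:
                    raise FormatError(f"line {lineno}: malformed molecule row")
                pending = (fields[1], float(fields[2]))
            elif fields[0] == "1":
                if pending is None:
                    raise FormatError(f"line {lineno}: label row without molecule row")
                mol_id, length = pending
                labels = np.array([float(x) for x in fields[1:] if x != ""], dtype=float)
                if len(labels) and np.any(np.diff(labels) < 0):
                    raise FormatError(f"line {lineno}: molecule {mol_id!r} labels not sorted")
                if len(labels) and (labels[0] < 0 or labels[-1] > length + 0.05):
                    raise FormatError(
                        f"line {lineno}: molecule {mol_id!r} label position exceeds length"
                    )
                molecules.append(Molecule(id=mol_id, length=length, labels=labels))
                pending = None
            else:
                raise FormatError(f"line {lineno}: unknown row type {fields[0]!r}")
    if pending is not None:
        raise FormatError(f"molecule {pending[0]!r} missing label row at end of file")
    header.pop(_BNX_VERSION_KEY, None)
    return BnxDataset(molecules=molecules, header=header)


def bnx_roundtrip(dataset: BnxDataset, path: Union[str, os.PathLike]) -> BnxDataset:
    """Write ``dataset`` to ``path`` and read it back."""
    write_bnx(dataset, path)
    return read_bnx(path)


# ---------------------------------------------------------------------------
# CMAP
# ---------------------------------------------------------------------------

_CMAP_COLUMNS = ["CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel",
                 "Position", "Coverage"]


def write_cmap(dataset: CmapDataset, path: Union[str, os.PathLike]) -> None:
    """Write maps in the minimal CMAP dialect (deterministic bytes)."""
    lines: List[str] = [f"# {_CMAP_VERSION_KEY}:\t0.1-min"]
    for key, value in dataset.header.items():
        if key == _CMAP_VERSION_KEY:
            continue
        lines.append(f"# {key}:\t{value}")
    lines.append("#h " + "\t".join(_CMAP_COLUMNS))
    for m in dataset.maps:
        labels = np.asarray(m.labels, dtype=float)
        if len(labels) and np.any(np.diff(labels) < 0):
            raise ValidationError(f"map {m.id!r}: unsorted labels on write")
        if len(labels) and (labels[0] < 0 or labels[-1] > m.length + 0.05):
            raise ValidationError(f"map {m.id!r}: labels outside [0, length]")
        support = getattr(m, "support", None)
        if support is None:
            support = np.ones(len(labels), dtype=int)
        n = len(labels)
        for site_idx, (pos, cov) in enumerate(zip(labels, support), start=1):
            lines.append(
                f"{m.id}\t{_fmt(m.length)}\t{n}\t{site_idx}\t1\t{_fmt(pos)}\t{int(cov)}"
            )
        # terminal channel-0 row marks the map end
        lines.append(f"{m.id}\t{_fmt(m.length)}\t{n}\t{n + 1}\t0\t{_fmt(m.length)}\t0")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cmap(path: Union[str, os.PathLike]) -> CmapDataset:
    header: Dict[str, str] = {}
    order: List[str] = []
    per_map: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#h"):
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header[key.strip()] = value.strip().lstrip("\t").strip()
                continue
            fields = line.split("\t")
            if len(fields) != len(_CMAP_COLUMNS):
                raise FormatError(f"line {lineno}: expected {len(_CMAP_COLUMNS)} columns")
            map_id, length_s, _nsites, _site_id, channel, pos_s, cov_s = fields
            if map_id not in per_map:
                per_map[map_id] = {"length": float(length_s), "labels": [], "support": []}
                order.append(map_id)
            if channel == "0":
                continue
            per_map[map_id]["labels"].append(float(pos_s))
            per_map[map_id]["support"].append(int(cov_s))
    maps: List[LabelMap] = []
    for map_id in order:
        entry = per_map[map_id]
        labels = np.array(entry["labels"], dtype=float)
        support = np.array(entry["support"], dtype=int)
        if len(labels) and np.any(np.diff(labels) < 0):
            raise FormatError(f"map {map_id!r}: labels not sorted")
        if len(labels) and (labels[0] < 0 or labels[-1] > entry["length"] + 0.05):
            raise FormatError(f"map {map_id!r}: label position exceeds map length")
        if len(support) and np.any(support > 1):
            maps.append(ConsensusMap(id=map_id, length=entry["length"], labels=labels,
                                     support=support))
        else:
            maps.append(LabelMap(id=map_id, length=entry["length"], labels=labels))
    header.pop(_CMAP_VERSION_KEY, None)
    return CmapDataset(maps=maps, header=header)


def cmap_roundtrip(dataset: CmapDataset, path: Union[str, os.PathLike]) -> CmapDataset:
    """Write ``dataset`` to ``path`` and read it back."""
    write_cmap(dataset, path)
    return read_cmap(path)
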