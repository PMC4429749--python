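"""Genomic coordinate conventions, readers/writers, and promoter extraction.

All coordinates are 0-based, half-open internally. BED and bedGraph are
native to that convention; GFF3 (1-based, closed) is converted on read and
write. Signal tracks are dense per-base arrays, one per sequence, so that
windowed feature extraction reduces to array slicing.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator

__all__ = [
    "GenomicInterval",
    "PreMiRNA",
    "SignalTrack",
    "MotifAnnotation",
    "DEFAULT_ORGANELLES",
    "MOTIF_CLASSES",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "upstream_window",
    "extract_promoter",
]

#: Organellar sequences excluded from TSS training by default. Chloroplast
#: and mitochondrial genes lack the TSS-tag / ChIP-seq evidence the
#: classifier relies on.
DEFAULT_ORGANELLES = frozenset({"ChrC", "ChrM", "Pt", "Mt"})

#: The five core-promoter motif classes recognised near plant TSSs.
MOTIF_CLASSES = ("Y_patch", "Inr", "CA", "GA", "REG")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware location on a named sequence (0-based, half-open)."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5' end (the start for +, end-1 for -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PreMiRNA:
    """A miRNA precursor locus.

    ``intragenic`` marks precursors embedded on the same strand of an
    annotated gene; for those the host gene's TSS stands in for the
    miRNA TSS downstream.
    """

    id: str
    locus: GenomicInterval
    intragenic: bool = False
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if self.intragenic != (self.host_gene is not None):
            raise ValueError(
                "intragenic must be True exactly when host_gene is set")


class SignalTrack:
    """Dense per-base, non-negative coverage for one chromatin/tag feature.

    Parameters
    ----------
    name:
        Feature label, e.g. ``tss_tags``, ``h3k4me3``, ``h3k9ac``, ``h3``.
    values:
        Mapping seqid -> 1-D float array of per-base values.
    """

    def __init__(self, name: str, values: Mapping[str, np.ndarray]):
        self.name = name
        self.values: dict[str, np.ndarray] = {}
        for seqid, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"track {name}/{seqid}: values must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"track {name}/{seqid}: negative values")
            self.values[seqid] = arr
        self._cumsum: dict[str, np.ndarray] = {}

    def cumsum(self, seqid: str) -> np.ndarray:
        """Cached prefix sums (length n+1); treat value arrays as immutable."""
        cs = self._cumsum.get(seqid)
        if cs is None:
            cs = np.concatenate([[0.0], np.cumsum(self.values[seqid])])
            self._cumsum[seqid] = cs
        return cs

    def __repr__(self) -> str:  # pragma: no cover
        return f"SignalTrack({self.name!r}, seqids={sorted(self.values)})"


@dataclass
class MotifAnnotation:
    """Genomic sites of one core-promoter motif class."""

    motif_class: str
    sites: list[GenomicInterval] = field(default_factory=list)
    allowed_classes: tuple[str, ...] = MOTIF_CLASSES

    def __post_init__(self) -> None:
        if self.motif_class not in self.allowed_classes:
            raise ValueError(
                f"unknown motif class {self.motif_class!r}; "
                f"allowed: {self.allowed_classes}")
        self._starts: dict[str, np.ndarray] | None = None

    def starts_by_seqid(self) -> dict[str, np.ndarray]:
        """Sorted arrays of site start positions, one per seqid (cached)."""
        if self._starts is None:
            by: dict[str, list[int]] = {}
            for s in self.sites:
                by.setdefault(s.seqid, []).append(s.start)
            self._starts = {k: np.sort(np.asarray(v, dtype=int))
                            for k, v in by.items()}
        return self._starts


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{seqid: upper-cased sequence}``.

    Duplicate record ids and empty files are errors.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA record id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for seqid in records:
            fh.write(f">{seqid}\n")
            seq = records[seqid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3(path, feature_types: Iterable[str] | None = None
              ) -> pd.DataFrame:
    """Read GFF3 features into a DataFrame with 0-based half-open coords.

    Columns: seqid, source, type, start, end, strand, id, attributes
    (the raw attribute dict). ``feature_types`` filters on column 3.
    """
    wanted = set(feature_types) if feature_types is not None else None
    rows = []
    for feat in DataIterator(str(path)):
        if wanted is not None and feat.featuretype not in wanted:
            continue
        fid = feat.attributes.get("ID", [None])[0] \
            or feat.attributes.get("Name", [None])[0]
        rows.append({
            "seqid": feat.seqid,
            "source": feat.source,
            "type": feat.featuretype,
            "start": feat.start - 1,  # GFF3 is 1-based closed
            "end": feat.end,
            "strand": feat.strand,
            "id": fid,
            "attributes": dict(feat.attributes),
        })
    return pd.DataFrame(
        rows, columns=["seqid", "source", "type", "start", "end",
                       "strand", "id", "attributes"])


def read_bed(path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame; coordinates stay 0-based."""
    names = ["seqid", "start", "end", "name", "score", "strand"]
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(intervals: Iterable, path, names: Iterable[str] | None = None,
              scores: Iterable[float] | None = None) -> None:
    intervals = list(intervals)
    names = list(names) if names is not None else ["."] * len(intervals)
    scores = list(scores) if scores is not None else [0.0] * len(intervals)
    with open(path, "wt") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.seqid}\t{iv.start}\t{iv.end}\t{name}\t"
                     f"{score:g}\t{iv.strand}\n")


def read_bedgraph(path, genome_lengths: Mapping[str, int],
                  name: str = "custom") -> SignalTrack:
    """Expand a 4-column bedGraph into a dense :class:`SignalTrack`.

    Overlapping records are summed (coverage semantics). Records that run
    past the sequence end, negative values, and unknown seqids are errors.
    """
    values = {sid: np.zeros(n, dtype=float)
              for sid, n in genome_lengths.items()}
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"bedGraph record {i}: expected 4 columns, "
                    f"got {len(parts)}")
            sid, start, end, val = parts[0], int(parts[1]), int(parts[2]), \
                float(parts[3])
            if sid not in values:
                raise ValueError(f"bedGraph record {i}: unknown seqid {sid!r}")
            if val < 0:
                raise ValueError(f"bedGraph record {i}: negative value {val}")
            if not (0 <= start < end <= genome_lengths[sid]):
                raise ValueError(
                    f"bedGraph record {i}: interval [{start}, {end}) outside "
                    f"{sid} of length {genome_lengths[sid]}")
            values[sid][start:end] += val
    return SignalTrack(name, values)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Run-length encode a track to bedGraph; zero runs are omitted."""
    with open(path, "wt") as fh:
        for sid in sorted(track.values):
            arr = track.values[sid]
            if arr.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{sid}\t{s}\t{e}\t{v:g}\n")


def upstream_window(locus: GenomicInterval, length: int,
                    seq_length: int | None = None) -> GenomicInterval:
    """The window of ``length`` bases immediately upstream of ``locus``.

    Strand-aware: upstream of a minus-strand locus lies at higher
    coordinates. Clipped at sequence boundaries; a window with no
    remaining space raises ``ValueError``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if locus.strand == "+":
        start, end = max(0, locus.start - length), locus.start
    else:
        start = locus.end
        end = locus.end + length
        if seq_length is not None:
            end = min(end, seq_length)
    if start >= end:
        raise ValueError(
            f"empty upstream window for {locus.seqid}:{locus.start}-"
            f"{locus.end}({locus.strand})")
    return GenomicInterval(locus.seqid, start, end, locus.strand)


def extract_promoter(genome: Mapping[str, str], seqid: str, tss: int,
                     strand: str, length: int = 1000) -> str:
    """Extract the promoter sequence upstream of a TSS.

    For strand '+' this is the ``length`` bases ending at (and excluding)
    the TSS; for strand '-' the ``length`` bases starting just after the
    TSS, reverse-complemented, so the returned string always reads 5'->3'
    toward the TSS. Truncated with a warning when the sequence boundary
    clips the window.
    """
    seq = genome[seqid]
    if not (0 <= tss < len(seq)):
        raise ValueError(f"TSS {tss} outside {seqid} of length {len(seq)}")
    if strand == "+":
        start = tss - length
        if start < 0:
            warnings.warn(
                f"promoter at {seqid}:{tss}(+) truncated to {tss} bp")
            start = 0
        return seq[start:tss]
    end = tss + 1 + length
    if end > len(seq):
        warnings.warn(
            f"promoter at {seqid}:{tss}(-) truncated to "
            f"{len(seq) - tss - 1} bp")
        end = len(seq)
    return reverse_complement(seq[tss + 1:end])
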