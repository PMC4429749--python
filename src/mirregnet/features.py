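"""Binned feature profiles around genomic anchors.

Chromatin signal (TSS tags, H3K4me3, H3K9ac, nucleosome H3) and
core-promoter motif occurrences are summarised as fixed-width bins in a
strand-oriented window around an anchor position. Single-anchor profiles
feed the TSS classifier; summed profiles over many anchors give the
meta-profile view (signal enrichment/depletion around verified TSSs).

Bins run 5'->3' relative to the anchor's strand: for a minus-strand
anchor the bin order is mirrored, so bin 0 is always the far-upstream
bin. The bin statistic is the sum (cumulative counts, not means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic import MotifAnnotation, SignalTrack

__all__ = [
    "FeatureProfile",
    "FeatureVector",
    "window_signal",
    "motif_density",
    "meta_profile",
    "build_feature_vector",
    "batch_feature_matrix",
    "profiles_to_frame",
    "plot_profiles",
]


@dataclass
class FeatureProfile:
    """Binned values of one feature in a window around an anchor."""

    feature_name: str
    bin_values: np.ndarray
    bin_size: int
    span: int

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if self.span % self.bin_size != 0:
            raise ValueError("bin_size must divide span")
        if len(self.bin_values) != 2 * self.span // self.bin_size:
            raise ValueError(
                f"expected {2 * self.span // self.bin_size} bins, "
                f"got {len(self.bin_values)}")

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)


@dataclass
class FeatureVector:
    """Concatenated binned profiles for one candidate position."""

    seqid: str
    position: int
    strand: str
    values: np.ndarray
    feature_layout: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != sum(n for _, n in self.feature_layout):
            raise ValueError("values length does not match feature_layout")


def _check_window(span: int, bin_size: int) -> int:
    if span <= 0:
        raise ValueError("span must be positive")
    if bin_size <= 0 or span % bin_size != 0:
        raise ValueError("bin_size must be positive and divide span")
    return 2 * span // bin_size


def _signal_bins(track: SignalTrack, seqid: str, anchor: int, strand: str,
                 span: int, bin_size: int) -> np.ndarray:
    n_bins = _check_window(span, bin_size)
    arr = track.values[seqid]
    cs = track.cumsum(seqid)
    # Minus-strand windows reflect positions around the anchor (rel =
    # anchor - p with the same half-open binning), which shifts the edge
    # grid by one base before the bin order is mirrored.
    base = anchor if strand == "+" else anchor + 1
    edges = base - span + bin_size * np.arange(n_bins + 1)
    edges = np.clip(edges, 0, arr.size)
    bins = cs[edges[1:]] - cs[edges[:-1]]
    return bins[::-1] if strand == "-" else bins


def window_signal(track: SignalTrack, seqid: str, anchor: int, strand: str,
                  span: int = 1000, bin_size: int = 200) -> FeatureProfile:
    """Sum per-base signal into bins around an anchor position.

    Out-of-bounds bins are zero-filled; bin order is 5'->3' on the
    anchor's strand.
    """
    if seqid not in track.values:
        raise KeyError(f"seqid {seqid!r} not in track {track.name!r}")
    bins = _signal_bins(track, seqid, anchor, strand, span, bin_size)
    return FeatureProfile(track.name, bins, bin_size, span)


def motif_density(annotation: MotifAnnotation, seqid: str, anchor: int,
                  strand: str, span: int = 1000, bin_size: int = 200
                  ) -> FeatureProfile:
    """Count motif-site starts per bin around an anchor.

    A site whose start falls exactly on a bin boundary belongs to the
    downstream bin (half-open bins). On the minus strand the relative
    coordinate is mirrored before binning.
    """
    n_bins = _check_window(span, bin_size)
    starts = annotation.starts_by_seqid().get(seqid)
    bins = np.zeros(n_bins)
    if starts is not None and starts.size:
        rel = (starts - anchor) if strand == "+" else (anchor - starts)
        idx = (rel + span) // bin_size
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(bins, idx[ok].astype(int), 1.0)
    return FeatureProfile(annotation.motif_class, bins, bin_size, span)


def meta_profile(anchors: Sequence[tuple[str, int, str]],
                 source: SignalTrack | MotifAnnotation,
                 span: int = 5000, bin_size: int = 200) -> FeatureProfile:
    """Element-wise sum of per-anchor profiles over many anchors.

    Anchors are (seqid, position, strand) triples. The cumulative sum
    (not the mean) is reported, matching the accumulative-count view of
    signal enrichment around verified TSSs.
    """
    if not anchors:
        raise ValueError("meta_profile needs at least one anchor")
    single = window_signal if isinstance(source, SignalTrack) else motif_density
    total = None
    for seqid, pos, strand in anchors:
        prof = single(source, seqid, pos, strand, span=span, bin_size=bin_size)
        total = prof.bin_values if total is None else total + prof.bin_values
    name = source.name if isinstance(source, SignalTrack) \
        else source.motif_class
    return FeatureProfile(name, total, bin_size, span)


def _canonical_order(feature_set: Iterable[str],
                     tracks: Mapping[str, SignalTrack],
                     motifs: Mapping[str, MotifAnnotation]) -> list[str]:
    available = set(tracks) | set(motifs)
    feature_set = set(feature_set)
    unknown = feature_set - available
    if unknown:
        raise ValueError(
            f"unknown features {sorted(unknown)}; valid: {sorted(available)}")
    # canonical order is alphabetical, independent of input order
    return sorted(feature_set)


def build_feature_vector(seqid: str, anchor: int, strand: str,
                         tracks: Mapping[str, SignalTrack],
                         motifs: Mapping[str, MotifAnnotation],
                         feature_set: Iterable[str],
                         span: int = 1000, bin_size: int = 200
                         ) -> FeatureVector:
    """Concatenate selected features' binned profiles for one position.

    Features are concatenated in canonical (alphabetical) order so the
    layout is independent of the order the caller lists them in.
    """
    order = _canonical_order(feature_set, tracks, motifs)
    parts, layout = [], []
    for name in order:
        if name in tracks:
            prof = window_signal(tracks[name], seqid, anchor, strand,
                                 span, bin_size)
        else:
            prof = motif_density(motifs[name], seqid, anchor, strand,
                                 span, bin_size)
        parts.append(prof.bin_values)
        layout.append((name, prof.n_bins))
    return FeatureVector(seqid, anchor, strand, np.concatenate(parts),
                         tuple(layout))


def batch_feature_matrix(seqid: str, positions: np.ndarray, strand: str,
                         tracks: Mapping[str, SignalTrack],
                         motifs: Mapping[str, MotifAnnotation],
                         feature_set: Iterable[str],
                         span: int = 1000, bin_size: int = 200
                         ) -> tuple[np.ndarray, tuple[tuple[str, int], ...]]:
    """Feature matrix (n_positions x n_features) for many anchors at once.

    Equivalent to stacking :func:`build_feature_vector` outputs; used by
    the upstream TSS scan where thousands of positions are scored.
    """
    order = _canonical_order(feature_set, tracks, motifs)
    positions = np.asarray(positions, dtype=int)
    n_bins = _check_window(span, bin_size)
    blocks, layout = [], []
    for name in order:
        if name in tracks:
            track = tracks[name]
            cs = track.cumsum(seqid)
            size = track.values[seqid].size
            base = positions if strand == "+" else positions + 1
            edges = (base[:, None] - span
                     + bin_size * np.arange(n_bins + 1)[None, :])
            edges = np.clip(edges, 0, size)
            bins = cs[edges[:, 1:]] - cs[edges[:, :-1]]
            if strand == "-":
                bins = bins[:, ::-1]
        else:
            starts = motifs[name].starts_by_seqid().get(
                seqid, np.empty(0, dtype=int))
            bins = np.empty((positions.size, n_bins))
            for j in range(n_bins):
                if strand == "+":
                    lo = positions - span + j * bin_size
                else:
                    # rel = anchor - start in [-span + j*b, -span + (j+1)*b)
                    lo = positions + span - (j + 1) * bin_size + 1
                bins[:, j] = (np.searchsorted(starts, lo + bin_size)
                              - np.searchsorted(starts, lo))
        blocks.append(bins)
        layout.append((name, n_bins))
    return np.hstack(blocks), tuple(layout)


def profiles_to_frame(profiles: Sequence[FeatureProfile]):
    """Tidy DataFrame of profiles: one row per (feature, bin)."""
    import pandas as pd

    rows = []
    for p in profiles:
        offsets = -p.span + p.bin_size * np.arange(p.n_bins)
        for off, val in zip(offsets, p.bin_values):
            rows.append({"feature": p.feature_name, "offset": int(off),
                         "value": float(val)})
    return pd.DataFrame(rows)


def plot_profiles(profiles: Sequence[FeatureProfile], path) -> None:
    """Plot meta-profiles (one line per feature) around the anchor."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for p in profiles:
        offsets = -p.span + p.bin_size * (np.arange(p.n_bins) + 0.5)
        ax.plot(offsets, p.bin_values, label=p.feature_name)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel("accumulated signal / site count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
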