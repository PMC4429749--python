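"""Match-style PWM scanning and coTFBS over-representation statistics.

A binding site model is a position frequency matrix (PWM). Scanning uses
information-weighted similarity scores normalised to [0, 1]:

    I(i)   = sum_b f(i,b) * ln(4 f(i,b))          (0*ln 0 := 0)
    MSS    = (Current - Min) / (Max - Min)
    Current = sum_i I(i) * f(i, b_i)
    Max/Min = sum_i I(i) * max_b/min_b f(i,b)

The matrix similarity score (MSS) uses all positions; the core
similarity score (CSS) restricts to the 5 consecutive positions with the
highest summed information content. A hit requires both scores to clear
their thresholds, on either strand.

The coTFBS statistic asks whether a given TFBS is over-represented in
the promoters of one miRNA's coexpressed gene group relative to all
groups in the run, via an upper-tail hypergeometric p-value on
promoter-presence counts, combined with the within-group frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic import reverse_complement

__all__ = [
    "PWM",
    "TfbsHit",
    "CoTFBSStat",
    "information_vector",
    "core_positions",
    "matrix_similarity",
    "core_similarity",
    "scan_sequence",
    "scan_promoter",
    "cotfbs_frequency",
    "hypergeom_pvalue",
    "group_statistics",
    "candidate_tfs",
    "read_jaspar",
    "write_jaspar",
    "read_pwm_tsv",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
CORE_LENGTH = 5


@dataclass(frozen=True)
class PWM:
    """A position frequency matrix over A, C, G, T.

    ``matrix`` has shape (L, 4); each row sums to 1 after construction.
    Zero frequencies are legal (the information weight defines
    0*ln 0 = 0); an optional pseudocount is added before renormalisation
    when a row contains an exact zero, for callers who prefer softened
    matrices.
    """

    id: str
    matrix: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 2:
            raise ValueError(
                f"PWM {self.id!r}: matrix must be (L>=2, 4), got {m.shape}")
        if np.any(m < 0):
            raise ValueError(f"PWM {self.id!r}: negative frequencies")
        if np.any(m.sum(axis=1) <= 0):
            raise ValueError(f"PWM {self.id!r}: empty position row")
        if self.pseudocount and np.any(m == 0):
            m = m + self.pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))


@dataclass(frozen=True)
class TfbsHit:
    """One PWM match in one promoter (promoter-relative coordinates)."""

    pwm_id: str
    promoter_id: str
    offset: int
    strand: str
    matrix_similarity: float
    core_similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.matrix_similarity <= 1.0
                and 0.0 <= self.core_similarity <= 1.0):
            raise ValueError("similarity scores must lie in [0, 1]")


@dataclass(frozen=True)
class CoTFBSStat:
    """Hypergeometric counts for one TFBS in one coexpressed group.

    Counts are promoter-presence detections: each (promoter, PWM) pair
    contributes at most 1. N/K range over all groups in the run, n/k
    over the focal group; ``frequency`` is the fraction of the group's
    promoters containing at least one hit of this PWM.
    """

    pwm_id: str
    group_id: str
    N: int
    K: int
    n: int
    k: int
    frequency: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N
                and self.n <= self.N):
            raise ValueError(
                f"inconsistent counts N={self.N} K={self.K} "
                f"n={self.n} k={self.k}")
        if not (0 <= self.frequency <= 1):
            raise ValueError("frequency must lie in [0, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def information_vector(pwm: PWM) -> np.ndarray:
    """Per-position information weights I(i) = sum_b f ln(4f), in [0, ln 4]."""
    m = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m > 0, m * np.log(4.0 * m), 0.0)
    return terms.sum(axis=1)


def core_positions(pwm: PWM) -> tuple[int, int]:
    """Start/end (half-open) of the 5 consecutive most informative positions.

    Ties go to the leftmost window. Matrices shorter than 5 fall back to
    the full length with a warning.
    """
    L = len(pwm)
    if L < CORE_LENGTH:
        warnings.warn(
            f"PWM {pwm.id!r} shorter than {CORE_LENGTH}; core = full matrix")
        return 0, L
    info = information_vector(pwm)
    sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
    start = int(np.argmax(sums))  # argmax returns the leftmost maximum
    return start, start + CORE_LENGTH


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to indices 0-3; any ambiguity code maps to 4."""
    idx = np.full(len(seq), 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(b)
        idx[mask] = i
    return idx


def _window_scores(pwm: PWM, idx: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Similarity over positions [lo, hi) of the PWM for every window.

    Ambiguous bases contribute the position's minimum frequency.
    """
    info = information_vector(pwm)[lo:hi]
    m = pwm.matrix[lo:hi]
    weighted = info[:, None] * m                       # (L', 4)
    lookup = np.column_stack([weighted, (info * m.min(axis=1))[:, None]])
    lmax = (info * m.max(axis=1)).sum()
    lmin = (info * m.min(axis=1)).sum()
    n_win = idx.size - len(pwm) + 1
    if n_win <= 0:
        return np.empty(0)
    current = np.zeros(n_win)
    for i in range(hi - lo):
        current += lookup[i][idx[lo + i: lo + i + n_win]]
    if lmax == lmin:  # zero-information matrix
        warnings.warn(f"PWM {pwm.id!r} carries no information; score := 0")
        return np.zeros(n_win)
    return (current - lmin) / (lmax - lmin)


def matrix_similarity(pwm: PWM, window_sequence: str) -> float:
    """MSS of one window (length must equal the PWM length)."""
    if len(window_sequence) != len(pwm):
        raise ValueError(
            f"window length {len(window_sequence)} != PWM length {len(pwm)}")
    s = _window_scores(pwm, _encode(window_sequence.upper()), 0, len(pwm))
    return float(np.clip(s[0], 0.0, 1.0))


def core_similarity(pwm: PWM, window_sequence: str) -> float:
    """CSS of one window: MSS restricted to the 5-position core."""
    if len(window_sequence) != len(pwm):
        raise ValueError(
            f"window length {len(window_sequence)} != PWM length {len(pwm)}")
    lo, hi = core_positions(pwm)
    s = _window_scores(pwm, _encode(window_sequence.upper()), lo, hi)
    return float(np.clip(s[0], 0.0, 1.0))


def scan_sequence(sequence: str, pwm: PWM, core_threshold: float = 0.75,
                  matrix_threshold: float = 0.85,
                  promoter_id: str = "promoter") -> list[TfbsHit]:
    """Scan both strands of one sequence with one PWM.

    A hit requires core >= core_threshold AND matrix >= matrix_threshold.
    Minus-strand matches are reported at the forward-strand offset of
    the site's leftmost base. Hits are sorted by offset, then strand.
    """
    sequence = sequence.upper()
    L = len(pwm)
    hits: list[TfbsHit] = []
    if len(sequence) < L:
        return hits
    lo, hi = core_positions(pwm)
    for strand, seq in (("+", sequence),
                        ("-", reverse_complement(sequence))):
        idx = _encode(seq)
        mss = np.clip(_window_scores(pwm, idx, 0, L), 0.0, 1.0)
        css = np.clip(_window_scores(pwm, idx, lo, hi), 0.0, 1.0)
        keep = np.flatnonzero((mss >= matrix_threshold)
                              & (css >= core_threshold))
        for off in keep:
            fwd = off if strand == "+" else len(sequence) - L - off
            hits.append(TfbsHit(pwm.id, promoter_id, int(fwd), strand,
                                float(mss[off]), float(css[off])))
    hits.sort(key=lambda h: (h.offset, h.strand, h.pwm_id))
    return hits


def scan_promoter(sequence: str, pwms: Sequence[PWM],
                  core_threshold: float = 0.75,
                  matrix_threshold: float = 0.85,
                  promoter_id: str = "promoter") -> list[TfbsHit]:
    """Scan one promoter with a set of PWMs (both strands)."""
    if not (0 <= core_threshold <= 1 and 0 <= matrix_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    hits: list[TfbsHit] = []
    for pwm in pwms:
        hits.extend(scan_sequence(sequence, pwm, core_threshold,
                                  matrix_threshold, promoter_id))
    hits.sort(key=lambda h: (h.offset, h.pwm_id, h.strand))
    return hits


def cotfbs_frequency(hits_by_promoter: Mapping[str, Sequence[TfbsHit]],
                     pwm_id: str) -> float:
    """Fraction of group promoters containing >= 1 hit of a PWM.

    Multiple hits in one promoter count once (presence semantics).
    """
    if not hits_by_promoter:
        raise ValueError("group has no promoters")
    with_hit = sum(
        1 for hits in hits_by_promoter.values()
        if any(h.pwm_id == pwm_id for h in hits))
    return with_hit / len(hits_by_promoter)


def hypergeom_pvalue(N: int, K: int, n: int, k: int,
                     tail: str = "upper") -> float:
    """Hypergeometric probability for k successes in n draws.

    Drawing n from a population of N containing K successes:
    ``point`` gives P(X = k); ``upper`` (default, used for
    over-representation) gives P(X >= k). Evaluated in log space by
    scipy for large arguments.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got N={N} K={K} n={n}")
    if k < 0 or k > K or k > n:
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}")
    dist = stats.hypergeom(M=N, n=K, N=n)
    if tail == "point":
        return float(dist.pmf(k))
    if tail == "upper":
        return float(min(1.0, dist.sf(k - 1)))
    raise ValueError("tail must be 'point' or 'upper'")


def group_statistics(
    group_hits: Mapping[str, Mapping[str, Sequence[TfbsHit]]],
    pwm_ids: Sequence[str],
) -> dict[str, dict[str, CoTFBSStat]]:
    """coTFBS statistics for every (group, PWM) pair.

    ``group_hits`` maps group id -> promoter id -> hits for that
    promoter (the promoters of the miRNA and its coexpressed genes).
    Presence counts: N = all (promoter, PWM) detections over all groups,
    K = detections of one PWM over all groups, n = detections within
    one group, k = detections of that PWM within the group.
    """
    presence: dict[str, dict[str, int]] = {}
    for gid, promoters in group_hits.items():
        counts = {pid: 0 for pid in pwm_ids}
        for hits in promoters.values():
            for pid in {h.pwm_id for h in hits}:
                if pid in counts:
                    counts[pid] += 1
        presence[gid] = counts

    N = sum(sum(c.values()) for c in presence.values())
    K = {pid: sum(presence[g][pid] for g in presence) for pid in pwm_ids}

    out: dict[str, dict[str, CoTFBSStat]] = {}
    for gid, counts in presence.items():
        n = sum(counts.values())
        group_size = len(group_hits[gid])
        out[gid] = {}
        for pid in pwm_ids:
            k = counts[pid]
            freq = k / group_size if group_size else 0.0
            p = hypergeom_pvalue(N, K[pid], n, k) if N > 0 else 1.0
            out[gid][pid] = CoTFBSStat(pid, gid, N, K[pid], n, k, freq, p)
    return out


def candidate_tfs(group_id: str,
                  statistics: Mapping[str, Mapping[str, CoTFBSStat]],
                  freq_cutoff: float = 0.5, p_cutoff: float = 0.1
                  ) -> list[tuple[str, CoTFBSStat]]:
    """TF candidates for one miRNA group.

    Keeps PWMs with frequency strictly > ``freq_cutoff`` and p strictly
    < ``p_cutoff``; sorted by p ascending, ties by frequency descending,
    then PWM id. Needs at least two groups in the run — the
    hypergeometric background is all coexpressed groups.
    """
    if len(statistics) < 2:
        raise ValueError(
            "coTFBS over-representation needs >= 2 coexpressed groups "
            "as background")
    if group_id not in statistics:
        raise KeyError(f"unknown group {group_id!r}")
    rows = [(pid, st) for pid, st in statistics[group_id].items()
            if st.frequency > freq_cutoff and st.p_value < p_cutoff]
    rows.sort(key=lambda r: (r[1].p_value, -r[1].frequency, r[0]))
    return rows


# ---------------------------------------------------------------------------
# PWM I/O

def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-format matrices (counts or frequencies)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float).T
            out.append(PWM(m.matrix_id or m.name, counts))
    if not out:
        raise ValueError(f"no matrices found in {path}")
    return out


def write_jaspar(pwms: Sequence[PWM], path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (frequencies x ``scale``)."""
    with open(path, "wt") as fh:
        for p in pwms:
            fh.write(f">{p.id}\t{p.id}\n")
            counts = np.round(p.matrix * scale).astype(int)
            for bi, b in enumerate(_BASES):
                vals = " ".join(f"{v:4d}" for v in counts[:, bi])
                fh.write(f"{b}  [ {vals} ]\n")


def read_pwm_tsv(path) -> list[PWM]:
    """Read a plain 4-column TSV PWM file.

    Format: blocks started by ``>id`` lines followed by L rows of
    whitespace-separated A C G T frequencies.
    """
    pwms, pid, rows = [], None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if pid is not None:
                    pwms.append(PWM(pid, np.array(rows)))
                pid, rows = line[1:].split()[0], []
            else:
                rows.append([float(x) for x in line.split()])
    if pid is not None:
        pwms.append(PWM(pid, np.array(rows)))
    if not pwms:
        raise ValueError(f"no matrices found in {path}")
    return pwms
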