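"""The binary TSS classifier: training, validation, scanning, reporting.

Positives are experimentally verified TSSs of protein-coding genes with
a unique recorded TSS (organellar sequences excluded); negatives are
random genomic positions kept at a minimum distance from any known TSS.
Each anchor becomes a binned chromatin/motif feature vector; a
soft-margin SVM with an RBF kernel separates the classes. The trained
model scores every step-th position of the 10-kb window upstream of a
miRNA precursor, and non-maximum suppression plus ranking yields up to
ten TSS candidates, rank 1 being the representative TSS. Intragenic
precursors bypass the scan: the host gene's TSS represents them.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureVector, batch_feature_matrix
from .genomic import (DEFAULT_ORGANELLES, GenomicInterval, MotifAnnotation,
                      PreMiRNA, SignalTrack, upstream_window)

__all__ = [
    "TssRecord",
    "TrainingSet",
    "CvMetrics",
    "TrainedTssModel",
    "TssCandidate",
    "filter_training_tss",
    "sample_negatives",
    "cross_validate",
    "select_features",
    "train",
    "scan_upstream_tss",
    "resolve_intragenic",
    "build_training_set",
    "predict_mirna_tss",
    "evaluate_on_verified",
    "confusion_metrics",
]


@dataclass(frozen=True)
class TssRecord:
    """One experimentally recorded TSS of an annotated gene."""

    gene_id: str
    seqid: str
    position: int
    strand: str


@dataclass
class TrainingSet:
    """Labelled feature vectors for the TSS classifier."""

    positives: list[FeatureVector]
    negatives: list[FeatureVector]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both classes must be non-empty")
        layouts = {fv.feature_layout
                   for fv in self.positives + self.negatives}
        if len(layouts) != 1:
            raise ValueError("feature_layout differs across vectors")

    @property
    def layout(self) -> tuple[tuple[str, int], ...]:
        return self.positives[0].feature_layout

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack([fv.values for fv in self.positives]
                      + [fv.values for fv in self.negatives])
        y = np.concatenate([np.ones(len(self.positives)),
                            np.zeros(len(self.negatives))])
        return X, y

    def subset_features(self, feature_set: Iterable[str]) -> "TrainingSet":
        """Restrict every vector to the named features (layout sliced)."""
        keep = set(feature_set)
        unknown = keep - {name for name, _ in self.layout}
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")

        def slice_fv(fv: FeatureVector) -> FeatureVector:
            parts, layout, off = [], [], 0
            for name, n in fv.feature_layout:
                if name in keep:
                    parts.append(fv.values[off:off + n])
                    layout.append((name, n))
                off += n
            return FeatureVector(fv.seqid, fv.position, fv.strand,
                                 np.concatenate(parts), tuple(layout))

        return TrainingSet([slice_fv(v) for v in self.positives],
                           [slice_fv(v) for v in self.negatives],
                           self.provenance)


@dataclass
class CvMetrics:
    """Cross-validation performance, per fold and averaged.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/total.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    n_folds: int
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.accuracy,
                  self.precision):
            if not (0.0 <= v <= 1.0):
                raise ValueError("metrics must lie in [0, 1]")


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    total = tp + fn + tn + fp
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "accuracy": (tp + tn) / total if total else 0.0,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def filter_training_tss(tss_records: Sequence[TssRecord],
                        blacklist_seqids: Iterable[str] = DEFAULT_ORGANELLES
                        ) -> list[TssRecord]:
    """Positive anchors: one TSS per gene, unique-TSS genes only.

    Genes with more than one recorded TSS are dropped entirely, as are
    records on blacklisted (organellar) sequences.
    """
    blacklist = set(blacklist_seqids)
    by_gene: dict[str, list[TssRecord]] = {}
    for rec in tss_records:
        if rec.seqid in blacklist:
            continue
        by_gene.setdefault(rec.gene_id, []).append(rec)
    out = [recs[0] for _, recs in sorted(by_gene.items())
           if len(recs) == 1]
    if not out:
        warnings.warn("no training TSSs survive filtering")
    return out


def sample_negatives(genome_lengths: Mapping[str, int],
                     positive_anchors: Sequence[tuple[str, int]],
                     n: int, min_distance: int = 1000,
                     seed: int = 0) -> list[tuple[str, int]]:
    """Uniform random positions at least ``min_distance`` from any anchor.

    Deterministic for a fixed seed; sampling is without replacement over
    the allowed space, and an allowed space smaller than ``n`` is an
    error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    seqids = sorted(genome_lengths)
    masks = {sid: np.ones(genome_lengths[sid], dtype=bool) for sid in seqids}
    for sid, pos in positive_anchors:
        if sid in masks:
            lo = max(0, pos - min_distance)
            hi = min(genome_lengths[sid], pos + min_distance + 1)
            masks[sid][lo:hi] = False
    allowed = [(sid, p) for sid in seqids
               for p in np.flatnonzero(masks[sid])]
    if len(allowed) < n:
        raise ValueError(
            f"allowed space ({len(allowed)} positions) smaller than n={n}; "
            "reduce min_distance or n")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(allowed), size=n, replace=False)
    return [allowed[i] for i in sorted(idx)]


class _Scaler:
    """Per-feature z-scaling fitted on the training set."""

    def __init__(self, mean: np.ndarray, scale: np.ndarray):
        self.mean = mean
        self.scale = scale

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


DEFAULT_HYPERPARAMETERS = {"kernel": "rbf", "C": 1.0, "gamma": "auto"}


def _fit_svc(X: np.ndarray, y: np.ndarray,
             hyperparameters: Mapping | None, seed: int) -> SVC:
    hp = dict(DEFAULT_HYPERPARAMETERS)
    hp.update(hyperparameters or {})
    svc = SVC(random_state=seed, **hp)
    svc.fit(X, y)
    return svc


@dataclass
class TrainedTssModel:
    """A trained TSS classifier with its feature layout and scaling.

    The decision function is stored explicitly (support vectors, dual
    coefficients, intercept, kernel parameters), so a saved model is a
    plain archive of JSON metadata plus numeric blobs and prediction
    never needs the original training data.
    """

    feature_layout: tuple[tuple[str, int], ...]
    feature_set: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    kernel: str
    gamma: float
    span: int = 1000
    bin_size: int = 200
    metadata: dict = field(default_factory=dict)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """SVM decision values; positive means TSS-like."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        n_feat = sum(n for _, n in self.feature_layout)
        if X.shape[1] != n_feat:
            raise ValueError(
                f"feature layout mismatch: model expects {n_feat} values "
                f"({self.feature_layout}), got {X.shape[1]}")
        Z = (X - self.scaler_mean) / self.scaler_scale
        if self.kernel == "rbf":
            sq = (np.sum(Z ** 2, axis=1)[:, None]
                  + np.sum(self.support_vectors ** 2, axis=1)[None, :]
                  - 2.0 * Z @ self.support_vectors.T)
            k = np.exp(-self.gamma * np.maximum(sq, 0.0))
        elif self.kernel == "linear":
            k = Z @ self.support_vectors.T
        else:
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        return k @ self.dual_coef + self.intercept

    def score_vectors(self, vectors: Sequence[FeatureVector]) -> np.ndarray:
        for fv in vectors:
            if fv.feature_layout != self.feature_layout:
                raise ValueError(
                    f"feature layout mismatch: model trained on "
                    f"{self.feature_layout}, input has {fv.feature_layout}")
        return self.decision_scores(np.vstack([fv.values for fv in vectors]))

    def save(self, path) -> None:
        meta = {
            "feature_layout": [list(t) for t in self.feature_layout],
            "feature_set": list(self.feature_set),
            "intercept": self.intercept,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "span": self.span,
            "bin_size": self.bin_size,
            "metadata": self.metadata,
        }
        arrays = {
            "scaler_mean": self.scaler_mean,
            "scaler_scale": self.scaler_scale,
            "support_vectors": self.support_vectors,
            "dual_coef": self.dual_coef,
        }
        with zipfile.ZipFile(path, "w") as zf:
            # fixed entry timestamps keep saved models byte-reproducible
            def entry(name: str) -> zipfile.ZipInfo:
                return zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))

            zf.writestr(entry("meta.json"), json.dumps(meta, indent=1))
            for name, arr in arrays.items():
                buf = BytesIO()
                np.save(buf, arr)
                zf.writestr(entry(f"{name}.npy"), buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedTssModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = {name: np.load(BytesIO(zf.read(f"{name}.npy")))
                      for name in ("scaler_mean", "scaler_scale",
                                   "support_vectors", "dual_coef")}
        return cls(
            feature_layout=tuple((str(n), int(b))
                                 for n, b in meta["feature_layout"]),
            feature_set=tuple(meta["feature_set"]),
            intercept=float(meta["intercept"]),
            kernel=meta["kernel"], gamma=float(meta["gamma"]),
            span=int(meta["span"]), bin_size=int(meta["bin_size"]),
            metadata=meta["metadata"], **arrays)


def train(training_set: TrainingSet,
          feature_set: Iterable[str] | None = None,
          hyperparameters: Mapping | None = None,
          seed: int = 0, span: int = 1000, bin_size: int = 200,
          metadata: Mapping | None = None) -> TrainedTssModel:
    """Fit the TSS classifier on a training set.

    ``feature_set`` restricts to a subset of the layout's features;
    training is deterministic for a fixed seed.
    """
    if feature_set is not None:
        training_set = training_set.subset_features(feature_set)
    X, y = training_set.arrays()
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both classes")
    scaler = _Scaler.fit(X)
    svc = _fit_svc(scaler.transform(X), y, hyperparameters, seed)
    gamma = svc._gamma if hasattr(svc, "_gamma") else svc.gamma
    meta = {"seed": seed, "n_positives": len(training_set.positives),
            "n_negatives": len(training_set.negatives),
            "provenance": training_set.provenance}
    meta.update(metadata or {})
    return TrainedTssModel(
        feature_layout=training_set.layout,
        feature_set=tuple(name for name, _ in training_set.layout),
        scaler_mean=scaler.mean, scaler_scale=scaler.scale,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        kernel=svc.kernel, gamma=float(gamma),
        span=span, bin_size=bin_size, metadata=meta)


def cross_validate(training_set: TrainingSet, n_folds: int = 5,
                   seed: int = 0,
                   hyperparameters: Mapping | None = None,
                   classifier_factory=None) -> CvMetrics:
    """Stratified k-fold cross-validation of the TSS classifier.

    ``classifier_factory`` (returning an object with fit/predict) can
    replace the SVM, e.g. for testing the metric bookkeeping with a
    forced classifier. Reported metrics are means over folds. Sample
    order does not affect the result: fold assignment is tied to a
    deterministic ordering of the samples, not their input order.
    """
    X, y = training_set.arrays()
    if min(np.sum(y == 1), np.sum(y == 0)) < n_folds:
        raise ValueError(f"each class needs >= {n_folds} members")
    # canonical sample order, so permuting the input leaves folds unchanged
    order = np.lexsort(np.vstack([y, X.T]))
    X, y = X[order], y[order]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in skf.split(X, y):
        scaler = _Scaler.fit(X[train_idx])
        if classifier_factory is None:
            clf = _fit_svc(scaler.transform(X[train_idx]), y[train_idx],
                           hyperparameters, seed)
        else:
            clf = classifier_factory()
            clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        pred = clf.predict(scaler.transform(X[test_idx]))
        truth = y[test_idx]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        m = confusion_metrics(tp, fn, tn, fp)
        # identity: accuracy is the class-size-weighted mean of sens/spec
        P, Nn = tp + fn, tn + fp
        assert np.isclose(m["accuracy"],
                          (m["sensitivity"] * P + m["specificity"] * Nn)
                          / (P + Nn))
        per_fold.append(m)
    mean = {k: float(np.mean([f[k] for f in per_fold]))
            for k in ("sensitivity", "specificity", "accuracy", "precision")}
    return CvMetrics(mean["sensitivity"], mean["specificity"],
                     mean["accuracy"], mean["precision"], n_folds, per_fold)


def select_features(training_set: TrainingSet,
                    candidate_feature_sets: Sequence[Iterable[str]],
                    n_folds: int = 5, seed: int = 0,
                    hyperparameters: Mapping | None = None
                    ) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Evaluate candidate feature combinations by cross-validated accuracy.

    Returns the best feature set (ties: fewer features, then
    lexicographic) and the full results table, one row per combination.
    Combinations whose CV fails are recorded as failed rows.
    """
    if not candidate_feature_sets:
        raise ValueError("need at least one candidate feature set")
    rows = []
    for fs in candidate_feature_sets:
        fs = tuple(sorted(set(fs)))
        row: dict = {"feature_set": fs, "n_features": len(fs)}
        try:
            m = cross_validate(training_set.subset_features(fs),
                               n_folds=n_folds, seed=seed,
                               hyperparameters=hyperparameters)
            row.update(accuracy=m.accuracy, sensitivity=m.sensitivity,
                       specificity=m.specificity, precision=m.precision,
                       failed=False)
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            row.update(accuracy=np.nan, sensitivity=np.nan,
                       specificity=np.nan, precision=np.nan,
                       failed=True, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise ValueError("every candidate feature set failed")
    best = sorted(
        ok.itertuples(index=False),
        key=lambda r: (-r.accuracy, r.n_features, r.feature_set))[0]
    return tuple(best.feature_set), table


@dataclass
class TssCandidate:
    """A scored putative TSS for one miRNA."""

    mirna: str
    position: GenomicInterval
    score: float
    rank: int
    evidence: dict = field(default_factory=dict)
    est_support: bool | None = None
    conservation_support: bool | None = None


def scan_upstream_tss(model: TrainedTssModel, pre_mirna: PreMiRNA,
                      tracks: Mapping[str, SignalTrack],
                      motifs: Mapping[str, MotifAnnotation],
                      genome_lengths: Mapping[str, int],
                      window: int = 10000, step: int = 20,
                      top_k: int = 10, nms_radius: int = 200
                      ) -> list[TssCandidate]:
    """Score candidate TSS positions in the upstream window of a precursor.

    Every ``step``-th position is scored with the classifier; local
    non-maximum suppression within ``nms_radius`` keeps only local
    peaks; at most ``top_k`` candidates are returned, ranked by
    decreasing score (rank 1 = representative TSS). Equal scores are
    broken in favour of the position closer to the precursor 5' end.
    """
    locus = pre_mirna.locus
    try:
        win = upstream_window(locus, window,
                              genome_lengths.get(locus.seqid))
    except ValueError:
        warnings.warn(f"{pre_mirna.id}: empty upstream window")
        return []
    positions = np.arange(win.start, win.end, step)
    feats, layout = batch_feature_matrix(
        locus.seqid, positions, locus.strand, tracks, motifs,
        model.feature_set, span=model.span, bin_size=model.bin_size)
    if layout != model.feature_layout:
        raise ValueError(
            f"feature layout mismatch: model {model.feature_layout}, "
            f"scan produced {layout}")
    scores = model.decision_scores(feats)

    five_prime = locus.five_prime
    dist = np.abs(positions - five_prime)
    # sort by score desc, then proximity to the precursor, then position
    order = np.lexsort((positions, dist, -scores))
    kept: list[int] = []
    for i in order:
        if all(abs(positions[i] - positions[j]) > nms_radius for j in kept):
            kept.append(i)
        if len(kept) == top_k:
            break

    evidence_layout = model.feature_layout
    candidates = []
    for rank, i in enumerate(kept, start=1):
        off = 0
        evid = {}
        for name, nb in evidence_layout:
            evid[name] = float(feats[i, off:off + nb].sum())
            off += nb
        pos = int(positions[i])
        candidates.append(TssCandidate(
            pre_mirna.id,
            GenomicInterval(locus.seqid, pos, pos + 1, locus.strand),
            float(scores[i]), rank, evid))
    return candidates


def resolve_intragenic(pre_mirna: PreMiRNA,
                       host_tss: TssRecord) -> TssCandidate:
    """Represent an intragenic miRNA's TSS by its host gene's TSS."""
    if not pre_mirna.intragenic:
        raise ValueError(f"{pre_mirna.id} is not intragenic")
    if host_tss is None:
        raise ValueError(f"{pre_mirna.id}: host gene has no recorded TSS")
    pos = host_tss.position
    return TssCandidate(
        pre_mirna.id,
        GenomicInterval(host_tss.seqid, pos, pos + 1, host_tss.strand),
        score=float("inf"), rank=1,
        evidence={"host_gene": host_tss.gene_id})


def build_training_set(tss_records: Sequence[TssRecord],
                       tracks: Mapping[str, SignalTrack],
                       motifs: Mapping[str, MotifAnnotation],
                       genome_lengths: Mapping[str, int],
                       feature_set: Iterable[str] | None = None,
                       span: int = 1000, bin_size: int = 200,
                       min_distance: int = 1000,
                       blacklist_seqids: Iterable[str] = DEFAULT_ORGANELLES,
                       extra_avoid: Sequence[tuple[str, int]] = (),
                       seed: int = 0,
                       provenance: str = "") -> TrainingSet:
    """Assemble a labelled training set from verified TSS records.

    Positives are the unique-TSS genes surviving the blacklist filter;
    negatives are 1:1 matched random genomic positions at least
    ``min_distance`` from every recorded TSS (and from ``extra_avoid``
    anchors, e.g. known miRNA TSSs).
    """
    from .features import build_feature_vector

    if feature_set is None:
        feature_set = sorted(set(tracks) | set(motifs))
    positives = filter_training_tss(tss_records, blacklist_seqids)
    if not positives:
        raise ValueError("no positive anchors after filtering")
    avoid = ([(r.seqid, r.position) for r in tss_records]
             + list(extra_avoid))
    negatives = sample_negatives(genome_lengths, avoid, n=len(positives),
                                 min_distance=min_distance, seed=seed)
    pos_vecs = [build_feature_vector(r.seqid, r.position, r.strand,
                                     tracks, motifs, feature_set,
                                     span, bin_size)
                for r in positives]
    neg_vecs = [build_feature_vector(sid, pos, "+", tracks, motifs,
                                     feature_set, span, bin_size)
                for sid, pos in negatives]
    return TrainingSet(pos_vecs, neg_vecs, provenance)


def predict_mirna_tss(model: TrainedTssModel,
                      mirnas: Sequence[PreMiRNA],
                      tracks: Mapping[str, SignalTrack],
                      motifs: Mapping[str, MotifAnnotation],
                      genome_lengths: Mapping[str, int],
                      host_tss: Mapping[str, TssRecord] | None = None,
                      window: int = 10000, step: int = 20,
                      top_k: int = 10, nms_radius: int = 200
                      ) -> dict[str, list[TssCandidate]]:
    """TSS candidates for a cohort of precursors.

    Intragenic precursors with a recorded host TSS are represented by
    it (rank 1, no scan); everything else gets the upstream scan.
    """
    host_tss = host_tss or {}
    out: dict[str, list[TssCandidate]] = {}
    for pm in mirnas:
        if pm.intragenic and pm.host_gene in host_tss:
            out[pm.id] = [resolve_intragenic(pm, host_tss[pm.host_gene])]
        else:
            if pm.intragenic:
                warnings.warn(
                    f"{pm.id}: intragenic but host TSS unknown; scanning")
            out[pm.id] = scan_upstream_tss(
                model, pm, tracks, motifs, genome_lengths,
                window=window, step=step, top_k=top_k,
                nms_radius=nms_radius)
    return out


def evaluate_on_verified(candidates: Mapping[str, Sequence[TssCandidate]],
                         verified: Mapping[str, int],
                         tolerance_bp: int = 0) -> float:
    """Fraction of verified TSSs recovered within a distance tolerance.

    ``verified`` maps miRNA id -> TSS position; a verified TSS counts as
    recovered if any candidate for that miRNA lies within
    ``tolerance_bp``.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    if not verified:
        raise ValueError("verified TSS list is empty")
    hit = 0
    for mirna, pos in verified.items():
        cands = candidates.get(mirna, [])
        if any(abs(c.position.start - pos) <= tolerance_bp for c in cands):
            hit += 1
    return hit / len(verified)
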