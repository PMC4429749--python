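"""Training-set assembly, cross-validation, scanning and candidate rules."""

import numpy as np
import pytest

from mirregnet import tss
from mirregnet.features import FeatureVector
from mirregnet.genomic import GenomicInterval, PreMiRNA
from mirregnet.tss import (CvMetrics, TrainingSet, TssRecord,
                           build_training_set, confusion_metrics,
                           cross_validate, evaluate_on_verified,
                           filter_training_tss, predict_mirna_tss,
                           resolve_intragenic, sample_negatives,
                           select_features, train)


def fv(values, layout=None, pos=0):
    values = np.asarray(values, dtype=float)
    layout = layout or (("f", len(values)),)
    return FeatureVector("c", pos, "+", values, tuple(layout))


def toy_training_set(n=30, sep=6.0, seed=0, layout=None):
    """Linearly separable two-feature vectors."""
    rng = np.random.default_rng(seed)
    pos = [fv(rng.normal(sep, 1.0, 2), layout, i) for i in range(n)]
    neg = [fv(rng.normal(0.0, 1.0, 2), layout, i) for i in range(n)]
    return TrainingSet(pos, neg)


class TestFilterTrainingTss:
    RECORDS = [
        TssRecord("g1", "Chr1", 100, "+"),
        TssRecord("g2", "Chr1", 500, "+"),
        TssRecord("g2", "Chr1", 900, "+"),   # second TSS -> dropped
        TssRecord("g3", "ChrC", 50, "+"),    # organellar -> dropped
        TssRecord("g4", "Chr2", 300, "-"),
        TssRecord("g5", "Chr2", 700, "+"),
    ]

    def test_rules_combined(self):
        kept = filter_training_tss(self.RECORDS)
        assert sorted(r.gene_id for r in kept) == ["g1", "g4", "g5"]

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            assert filter_training_tss(
                [TssRecord("g", "ChrM", 5, "+")]) == []


class TestSampleNegatives:
    def test_deterministic_for_seed(self):
        lengths = {"c": 10000}
        pos = [("c", 3000), ("c", 7000)]
        a = sample_negatives(lengths, pos, 20, 500, seed=5)
        b = sample_negatives(lengths, pos, 20, 500, seed=5)
        assert a == b
        assert a != sample_negatives(lengths, pos, 20, 500, seed=6)

    def test_distance_constraint_exhaustive(self):
        lengths = {"c1": 5000, "c2": 5000}
        pos = [("c1", 1000), ("c1", 4000), ("c2", 2500)]
        negs = sample_negatives(lengths, pos, 50, 300, seed=1)
        for sid, p in negs:
            assert all(abs(p - q) >= 300 for s, q in pos if s == sid)

    def test_too_small_allowed_space(self):
        with pytest.raises(ValueError, match="allowed space"):
            sample_negatives({"c": 1000}, [("c", 500)], 10,
                             min_distance=2000, seed=0)


class TestCrossValidate:
    def test_forced_all_positive_classifier(self):
        class AllPositive:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.ones(len(X))

        m = cross_validate(toy_training_set(), n_folds=5, seed=0,
                           classifier_factory=AllPositive)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.accuracy == pytest.approx(0.5)

    def test_confusion_arithmetic(self):
        m = confusion_metrics(tp=9, fn=1, tn=8, fp=2)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(9 / 11, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_perfect_on_separable_data(self):
        m = cross_validate(toy_training_set(sep=10.0), n_folds=5, seed=0)
        assert (m.sensitivity, m.specificity, m.accuracy,
                m.precision) == (1.0, 1.0, 1.0, 1.0)

    def test_small_class_rejected(self):
        ts = toy_training_set(n=3)
        with pytest.raises(ValueError, match="class"):
            cross_validate(ts, n_folds=5)

    def test_permutation_invariance(self):
        ts = toy_training_set(n=25, sep=2.0, seed=3)
        m1 = cross_validate(ts, seed=4)
        shuffled = TrainingSet(list(reversed(ts.positives)),
                               list(reversed(ts.negatives)))
        m2 = cross_validate(shuffled, seed=4)
        assert m1.accuracy == m2.accuracy
        assert m1.per_fold == m2.per_fold


class TestSelectFeatures:
    def informative_set(self, seed=0):
        rng = np.random.default_rng(seed)
        layout = (("noise_feat", 2), ("tss_tags", 2))
        pos, neg = [], []
        for i in range(25):
            pos.append(fv(np.concatenate([rng.normal(0, 1, 2),
                                          rng.normal(5, 1, 2)]),
                          layout, i))
            neg.append(fv(np.concatenate([rng.normal(0, 1, 2),
                                          rng.normal(0, 1, 2)]),
                          layout, i))
        return TrainingSet(pos, neg)

    def test_single_candidate_identity(self):
        ts = self.informative_set()
        best, table = select_features(ts, [("tss_tags",)], seed=0)
        assert best == ("tss_tags",)
        assert len(table) == 1

    def test_informative_feature_selected(self):
        ts = self.informative_set()
        best, table = select_features(
            ts, [("noise_feat",), ("tss_tags",),
                 ("noise_feat", "tss_tags")], seed=0)
        assert "tss_tags" in best
        assert len(table) == 3

    def test_tie_broken_by_fewer_features(self):
        # duplicate-information candidates: accuracy ties, size-1 set wins
        ts = self.informative_set()
        best, _ = select_features(
            ts, [("tss_tags",), ("tss_tags", "noise_feat")], seed=0)
        tbl = select_features(
            ts, [("tss_tags",), ("tss_tags", "noise_feat")], seed=0)[1]
        if tbl["accuracy"].nunique() == 1:
            assert best == ("tss_tags",)


class TestTrainAndModel:
    def test_separable_training_accuracy(self):
        ts = toy_training_set(sep=8.0)
        model = train(ts, seed=0)
        X, y = ts.arrays()
        pred = (model.decision_scores(X) > 0).astype(float)
        assert (pred == y).all()

    def test_retrain_same_seed_identical(self):
        ts = toy_training_set(sep=2.0, seed=9)
        X, _ = ts.arrays()
        s1 = train(ts, seed=1).decision_scores(X)
        s2 = train(ts, seed=1).decision_scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_decision_matches_sklearn(self):
        from sklearn.svm import SVC

        ts = toy_training_set(sep=2.0, seed=2)
        X, y = ts.arrays()
        model = train(ts, seed=0)
        Z = (X - model.scaler_mean) / model.scaler_scale
        ref = SVC(kernel="rbf", C=1.0, gamma="auto", random_state=0)
        ref.fit(Z, y)
        np.testing.assert_allclose(model.decision_scores(X),
                                   ref.decision_function(Z), atol=1e-10)

    def test_layout_mismatch_rejected(self):
        model = train(toy_training_set(), seed=0)
        other = fv([1.0, 2.0, 3.0], (("g", 3),))
        with pytest.raises(ValueError, match="layout"):
            model.score_vectors([other])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet([fv([1, 2])], [])

    def test_save_load_round_trip(self, tmp_path):
        ts = toy_training_set(sep=3.0)
        model = train(ts, seed=0, metadata={"note": "toy"})
        model.save(tmp_path / "m.zip")
        back = tss.TrainedTssModel.load(tmp_path / "m.zip")
        X, _ = ts.arrays()
        np.testing.assert_allclose(back.decision_scores(X),
                                   model.decision_scores(X), atol=1e-12)
        assert back.feature_layout == model.feature_layout
        assert back.metadata["note"] == "toy"


class TestScan:
    def test_planted_peak_recovered(self, sim):
        training = build_training_set(
            sim.tss_records, sim.tracks, sim.motifs, sim.genome_lengths,
            seed=1,
            extra_avoid=[(s, p) for s, p, _ in sim.truth.true_tss.values()])
        model = train(training, seed=1)
        host = {r.gene_id: r for r in sim.tss_records}
        cands = predict_mirna_tss(model, sim.mirnas, sim.tracks, sim.motifs,
                                  sim.genome_lengths, host_tss=host)
        hits = 0
        for mid, (sid, pos, strand) in sim.truth.true_tss.items():
            top = cands[mid][0]
            assert top.rank == 1
            if abs(top.position.start - pos) <= 200:
                hits += 1
        assert hits >= 0.9 * len(sim.truth.true_tss)
        # candidate invariants: ranks consecutive, scores non-increasing
        for clist in cands.values():
            assert [c.rank for c in clist] == list(range(1, len(clist) + 1))
            scores = [c.score for c in clist]
            assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_candidates_respect_nms_radius(self, sim):
        training = build_training_set(
            sim.tss_records, sim.tracks, sim.motifs, sim.genome_lengths,
            seed=1)
        model = train(training, seed=1)
        scanned = [m for m in sim.mirnas if not m.intragenic][:3]
        for pm in scanned:
            cands = tss.scan_upstream_tss(model, pm, sim.tracks, sim.motifs,
                                          sim.genome_lengths)
            positions = [c.position.start for c in cands]
            for i, a in enumerate(positions):
                for b in positions[i + 1:]:
                    assert abs(a - b) > 200


class TestIntragenicAndEvaluation:
    def test_host_tss_represents_intragenic(self):
        pm = PreMiRNA("m", GenomicInterval("c", 5000, 5100, "-"),
                      intragenic=True, host_gene="g")
        host = TssRecord("g", "c", 5600, "-")
        cand = resolve_intragenic(pm, host)
        assert cand.rank == 1
        assert cand.position.start == 5600
        assert cand.position.strand == "-"
        assert cand.evidence == {"host_gene": "g"}

    def test_non_intragenic_rejected(self):
        pm = PreMiRNA("m", GenomicInterval("c", 5000, 5100))
        with pytest.raises(ValueError):
            resolve_intragenic(pm, TssRecord("g", "c", 100, "+"))

    def test_evaluate_fractions(self):
        def cand(mid, pos):
            return tss.TssCandidate(
                mid, GenomicInterval("c", pos, pos + 1), 1.0, 1)

        verified = {"m1": 100, "m2": 500, "m3": 900, "m4": 1300}
        cands = {"m1": [cand("m1", 100)], "m2": [cand("m2", 480)],
                 "m3": [cand("m3", 2000)]}
        assert evaluate_on_verified(cands, verified, 0) == 0.25
        assert evaluate_on_verified(cands, verified, 50) == 0.5
        assert evaluate_on_verified({}, verified, 10) == 0.0
        with pytest.raises(ValueError):
            evaluate_on_verified(cands, {}, 10)


def test_cv_metrics_range_validation():
    with pytest.raises(ValueError):
        CvMetrics(1.2, 0.5, 0.5, 0.5, 5)
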