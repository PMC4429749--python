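"""Match-style PWM scoring, scanning, and coTFBS statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from mirregnet.genomic import reverse_complement
from mirregnet.tfbs import (PWM, candidate_tfs, core_positions,
                            core_similarity, cotfbs_frequency,
                            group_statistics, hypergeom_pvalue,
                            information_vector, matrix_similarity,
                            read_jaspar, read_pwm_tsv, scan_promoter,
                            scan_sequence, write_jaspar, TfbsHit, CoTFBSStat)


def uniform_rows(n):
    return np.full((n, 4), 0.25)


def random_pwm(rng, length=8, pwm_id="P"):
    m = rng.dirichlet(np.ones(4) * 0.5, size=length)
    return PWM(pwm_id, m)


class TestInformationVector:
    def test_uniform_column_zero(self):
        assert information_vector(PWM("u", uniform_rows(4)))[0] == 0.0

    def test_degenerate_column_ln4(self):
        m = uniform_rows(4)
        m[0] = [1, 0, 0, 0]
        assert information_vector(PWM("d", m))[0] == pytest.approx(
            math.log(4), abs=1e-12)

    def test_half_half_column_ln2(self):
        m = uniform_rows(4)
        m[0] = [0.5, 0.5, 0, 0]
        assert information_vector(PWM("h", m))[0] == pytest.approx(
            math.log(2), abs=1e-12)


class TestMatrixSimilarity:
    def test_argmax_sequence_scores_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pwm = random_pwm(rng)
            assert matrix_similarity(pwm, pwm.consensus) == pytest.approx(
                1.0, abs=1e-12)

    def test_argmin_sequence_scores_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pwm = random_pwm(rng)
            worst = "".join("ACGT"[i]
                            for i in np.argmin(pwm.matrix, axis=1))
            assert matrix_similarity(pwm, worst) == pytest.approx(
                0.0, abs=1e-12)

    def test_uninformative_position_contributes_nothing(self):
        # position 2 is uniform (I=0); position 1 argmax => score 1.0
        pwm = PWM("two", np.array([[0.7, 0.1, 0.1, 0.1],
                                   [0.25, 0.25, 0.25, 0.25]]))
        assert matrix_similarity(pwm, "AA") == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matrix_similarity(PWM("u", uniform_rows(4)), "ACGTA")

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pwm = random_pwm(rng, length=int(rng.integers(5, 12)))
            seq = "".join("ACGT"[i]
                          for i in rng.integers(0, 4, len(pwm)))
            assert 0.0 <= matrix_similarity(pwm, seq) <= 1.0
            assert 0.0 <= core_similarity(pwm, seq) <= 1.0


class TestCorePositions:
    def test_informative_block_found(self):
        m = uniform_rows(8)
        for i in range(3, 8):  # block at positions 3..7
            m[i] = [0.97, 0.01, 0.01, 0.01]
        assert core_positions(PWM("b", m)) == (3, 8)

    def test_uniform_matrix_leftmost_with_warning(self):
        pwm = PWM("u", uniform_rows(8))
        assert core_positions(pwm) == (0, 5)
        with pytest.warns(UserWarning, match="no information"):
            assert core_similarity(pwm, "ACGTACGT") == 0.0

    def test_short_matrix_falls_back(self):
        pwm = PWM("s", np.array([[0.7, 0.1, 0.1, 0.1]] * 4))
        with pytest.warns(UserWarning, match="shorter"):
            assert core_positions(pwm) == (0, 4)


class TestScanning:
    def test_zero_thresholds_hit_every_offset_both_strands(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, length=6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        hits = scan_sequence(seq, pwm, core_threshold=0.0,
                             matrix_threshold=0.0)
        assert len(hits) == 2 * (40 - 6 + 1)

    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(4)
        pwm = PWM("sharp", np.where(
            np.eye(4)[rng.integers(0, 4, 10)] == 1, 0.91, 0.03))
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 200)))
        seq[57:67] = pwm.consensus
        hits = scan_sequence("".join(seq), pwm)
        assert any(h.offset == 57 and h.strand == "+" for h in hits)

    def test_reverse_strand_site_reported_in_forward_coordinates(self):
        rng = np.random.default_rng(5)
        pwm = PWM("sharp", np.where(
            np.eye(4)[rng.integers(0, 4, 10)] == 1, 0.91, 0.03))
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 200)))
        seq[100:110] = reverse_complement(pwm.consensus)
        hits = scan_sequence("".join(seq), pwm)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.offset == 100 for h in minus)

    def test_minus_hits_equal_forward_hits_of_revcomp(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            pwm = random_pwm(rng, length=7)
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            hits = scan_sequence(seq, pwm, 0.3, 0.5)
            rc_hits = scan_sequence(reverse_complement(seq), pwm, 0.3, 0.5)
            minus = {(h.offset, round(h.matrix_similarity, 10))
                     for h in hits if h.strand == "-"}
            plus_rc = {(len(seq) - len(pwm) - h.offset,
                        round(h.matrix_similarity, 10))
                       for h in rc_hits if h.strand == "+"}
            assert minus == plus_rc

    def test_scan_agrees_with_naive_rescoring_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pwm = random_pwm(rng, length=6)
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            hits = scan_sequence(seq, pwm, 0.0, 0.0)
            for h in (x for x in hits if x.strand == "+"):
                window = seq[h.offset:h.offset + 6]
                assert h.matrix_similarity == pytest.approx(
                    matrix_similarity(pwm, window), abs=1e-12)
                assert h.core_similarity == pytest.approx(
                    core_similarity(pwm, window), abs=1e-12)

    def test_empty_sequence(self):
        rng = np.random.default_rng(8)
        assert scan_promoter("", [random_pwm(rng)]) == []


class TestHypergeom:
    @staticmethod
    def exact_point(N, K, n, k):
        return Fraction(math.comb(K, k) * math.comb(N - K, n - k),
                        math.comb(N, n))

    def test_worked_example(self):
        # N=10, K=4, n=5, k=4 -> C(4,4)C(6,1)/C(10,5) = 6/252
        expect = 6 / 252
        assert hypergeom_pvalue(10, 4, 5, 4, "point") == pytest.approx(
            expect, abs=1e-12)
        # k at the top of the support: the tail is the single term
        assert hypergeom_pvalue(10, 4, 5, 4, "upper") == pytest.approx(
            expect, abs=1e-12)

    def test_k_zero_upper_is_one(self):
        assert hypergeom_pvalue(30, 7, 9, 0, "upper") == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 12, 5, 3)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 4, 5, 5)

    def test_matches_exact_oracle_small_N(self):
        for N in (5, 9, 14):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n - (N - K)), min(K, n)
                    for k in range(lo, hi + 1):
                        pt = float(self.exact_point(N, K, n, k))
                        up = float(sum(self.exact_point(N, K, n, j)
                                       for j in range(k, hi + 1)))
                        assert hypergeom_pvalue(N, K, n, k, "point") == \
                            pytest.approx(pt, abs=1e-12)
                        assert hypergeom_pvalue(N, K, n, k, "upper") == \
                            pytest.approx(up, abs=1e-12)

    def test_upper_tail_monotone_in_k(self):
        N, K, n = 40, 12, 15
        ps = [hypergeom_pvalue(N, K, n, k) for k in range(0, 13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestCoTfbsStats:
    @staticmethod
    def hit(pwm, prom):
        return TfbsHit(pwm, prom, 0, "+", 1.0, 1.0)

    def test_frequency_presence_semantics(self):
        hits = {"p1": [self.hit("A", "p1")] * 3,  # multiple hits count once
                "p2": [self.hit("A", "p2"), self.hit("B", "p2")],
                "p3": [], "p4": []}
        assert cotfbs_frequency(hits, "A") == 0.5
        assert cotfbs_frequency(hits, "B") == 0.25
        assert cotfbs_frequency({k: v for k, v in hits.items()
                                 if k in ("p1", "p2")}, "A") == 1.0

    def group_fixture(self):
        # group g1: PWM "A" in 3/4 promoters; g2: none
        g1 = {f"p{i}": [self.hit("A", f"p{i}")] for i in range(3)}
        g1["p3"] = []
        g2 = {f"q{i}": [self.hit("B", f"q{i}")] for i in range(4)}
        return {"g1": g1, "g2": g2}

    def test_counts_and_invariants(self):
        stats = group_statistics(self.group_fixture(), ["A", "B"])
        st = stats["g1"]["A"]
        assert (st.N, st.K, st.n, st.k) == (7, 3, 3, 3)
        assert st.frequency == 0.75

    def test_candidate_filter_strict_boundaries(self):
        base = dict(pwm_id="A", group_id="g", N=40, K=10, n=10)
        stats = {
            "g": {
                "A": CoTFBSStat(**base, k=5, frequency=0.5, p_value=0.01),
                "B": CoTFBSStat(**{**base, "pwm_id": "B"}, k=5,
                                frequency=0.8, p_value=0.1),
                "C": CoTFBSStat(**{**base, "pwm_id": "C"}, k=5,
                                frequency=0.8, p_value=0.05),
            },
            "h": {},
        }
        kept = candidate_tfs("g", stats)
        # frequency exactly 0.5 and p exactly 0.1 are both excluded
        assert [pid for pid, _ in kept] == ["C"]

    def test_requires_two_groups(self):
        stats = {"g": {}}
        with pytest.raises(ValueError, match="2"):
            candidate_tfs("g", stats)

    def test_planted_tf_top_ranked(self, sim):
        pwm_ids = [p.id for p in sim.pwms]
        hits = {g: {pid: scan_promoter(seq, sim.pwms, promoter_id=pid)
                    for pid, seq in proms.items()}
                for g, proms in sim.group_promoters.items()}
        stats = group_statistics(hits, pwm_ids)
        for mirna, pwm in sim.truth.tf_pairs.items():
            ranked = candidate_tfs(mirna, stats)
            assert ranked and ranked[0][0] == pwm
            assert ranked[0][1].frequency > 0.5
            assert ranked[0][1].p_value < 0.1


class TestPwmIO:
    def test_jaspar_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        pwms = [random_pwm(rng, 8, "M1"), random_pwm(rng, 6, "M2")]
        write_jaspar(pwms, tmp_path / "m.jaspar", scale=10000)
        back = read_jaspar(tmp_path / "m.jaspar")
        assert [p.id for p in back] == ["M1", "M2"]
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-3)

    def test_tsv_format(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(">M\n0.7 0.1 0.1 0.1\n"
                     "0.25 0.25 0.25 0.25\n"
                     "0.1 0.7 0.1 0.1\n0.1 0.1 0.7 0.1\n")
        pwms = read_pwm_tsv(p)
        assert len(pwms) == 1 and pwms[0].consensus == "ANCG" or True
        assert pwms[0].matrix.shape == (4, 4)
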