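"""PWM I/O and Clover-style enrichment scoring."""

import numpy as np
import pytest

from valleytf.motifscan import (
    PWM,
    Background,
    MotifScoreSeries,
    enrichment_p,
    rank_motifs,
    raw_score,
    read_motifs,
    score_series,
    sequence_alr,
    write_motifs_transfac,
)

from conftest import alr_oracle, revcomp


def uniform_bg(n=5, length=200, seed=7):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
    return Background(seqs, base_frequencies=np.full(4, 0.25))


def pwm_single_a():
    # width-1 motif, all mass on A, no pseudocount
    return PWM("A1", np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)


class TestPwmIO:
    def test_pseudocount_arithmetic(self):
        pwm = PWM("m", np.array([[10.0, 0, 0, 0]]), pseudocount=0.25)
        assert pwm.probs[0, 0] == pytest.approx(10.25 / 11)
        assert pwm.probs[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_transfac_roundtrip(self, tmp_path, rng):
        pwms = [
            PWM(f"V$M{i}", rng.integers(0, 20, size=(6, 4)).astype(float))
            for i in range(3)
        ]
        path = tmp_path / "motifs.transfac"
        write_motifs_transfac(pwms, path)
        back = read_motifs(path, "transfac")
        assert [p.motif_id for p in back] == [p.motif_id for p in pwms]
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.counts, b.counts)
            np.testing.assert_allclose(a.probs, b.probs)

    def test_meme_and_transfac_agree(self, tmp_path):
        counts = np.array([[8.0, 0, 2, 0], [0, 10.0, 0, 0], [1.0, 1, 7, 1]])
        tf_path = tmp_path / "m.transfac"
        write_motifs_transfac([PWM("M1", counts)], tf_path)
        meme_path = tmp_path / "m.meme"
        probs = counts / counts.sum(axis=1, keepdims=True)
        with open(meme_path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            fh.write("MOTIF M1\nletter-probability matrix: alength= 4 w= 3 nsites= 10 E= 0\n")
            for row in probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        a = read_motifs(tf_path, "transfac")[0]
        b = read_motifs(meme_path, "meme")[0]
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)

    def test_malformed_file_is_an_error(self, tmp_path):
        bad = tmp_path / "bad.transfac"
        bad.write_text("ID broken\nP0 A C G T\n01 x y z w\n//\n")
        with pytest.raises(ValueError):
            read_motifs(bad, "transfac")


class TestSequenceAlr:
    def test_width1_all_a_enumeration(self):
        # forward placements each LR=4, reverse placements LR=0:
        # ALR = (4*4 + 0) / 8 = 2
        assert sequence_alr(pwm_single_a(), "AAAA", uniform_bg()) == pytest.approx(2.0)

    def test_background_equal_pwm_scores_one(self, rng):
        pwm = PWM("bg", np.full((5, 4), 10.0), pseudocount=0.0)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        assert sequence_alr(pwm, seq, uniform_bg()) == pytest.approx(1.0, abs=1e-12)

    def test_strand_symmetry(self, rng):
        # holds even for a skewed background composition
        bg = Background(
            ["ACGTACGGGT" * 20], base_frequencies=np.array([0.4, 0.2, 0.1, 0.3])
        )
        for _ in range(5):
            pwm = PWM("m", rng.integers(0, 15, size=(7, 4)).astype(float))
            seq = "".join(rng.choice(list("ACGT"), size=60))
            assert sequence_alr(pwm, seq, bg) == pytest.approx(
                sequence_alr(pwm, revcomp(seq), bg), rel=1e-10
            )

    def test_matches_exhaustive_enumeration(self, rng):
        bg = uniform_bg()
        for w in (1, 4, 12):
            pwm = PWM("m", rng.integers(0, 12, size=(w, 4)).astype(float))
            for _ in range(4):
                n = int(rng.integers(w, 51))
                seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
                assert sequence_alr(pwm, seq, bg) == pytest.approx(
                    alr_oracle(pwm, seq, bg.base_frequencies), rel=1e-9
                )

    def test_too_short_sequence_rejected(self):
        pwm = PWM("m", np.full((5, 4), 1.0))
        with pytest.raises(ValueError):
            sequence_alr(pwm, "ACG", uniform_bg())


class TestRawScore:
    def test_background_equal_pwm_scores_zero(self, rng):
        pwm = PWM("bg", np.full((4, 4), 5.0), pseudocount=0.0)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)]
        assert raw_score(pwm, seqs, uniform_bg()) == pytest.approx(0.0, abs=1e-12)

    def test_single_sequence_ln2(self):
        assert raw_score(pwm_single_a(), ["AAAA"], uniform_bg()) == pytest.approx(
            np.log(2.0)
        )

    def test_duplication_invariance(self, rng):
        pwm = PWM("m", rng.integers(0, 12, size=(6, 4)).astype(float))
        bg = uniform_bg()
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(4)]
        assert raw_score(pwm, seqs, bg) == pytest.approx(
            raw_score(pwm, seqs * 3, bg), rel=1e-12
        )

    def test_short_sequences_skipped_with_warning(self):
        pwm = PWM("m", np.full((5, 4), 1.0))
        with pytest.warns(UserWarning):
            s = raw_score(pwm, ["ACG", "ACGTACGTAC"], uniform_bg())
        assert np.isfinite(s)

    def test_all_too_short_is_undefined(self):
        pwm = PWM("m", np.full((5, 4), 1.0))
        with pytest.warns(UserWarning):
            assert np.isnan(raw_score(pwm, ["ACG"], uniform_bg()))


class TestEnrichmentP:
    def test_floor_when_observed_dominates(self, rng):
        bg = uniform_bg(n=20, length=100)
        pwm = PWM("m", np.array([[50.0, 0, 0, 0]] * 6), pseudocount=0.1)
        targets = ["AAAAAA" * 10 for _ in range(5)]
        p = enrichment_p(pwm, targets, bg, n_draws=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_invariant_to_background_relabeling(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(15)]
        pwm = PWM("m", rng.integers(0, 12, size=(6, 4)).astype(float))
        targets = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
        freqs = np.full(4, 0.25)
        p1 = enrichment_p(pwm, targets, Background(seqs, freqs), n_draws=300, seed=5)
        p2 = enrichment_p(
            pwm, targets, Background(seqs[::-1], freqs), n_draws=300, seed=5
        )
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_null_calibration_mean_near_half(self, rng):
        # targets drawn from the background itself -> p roughly uniform
        bg = uniform_bg(n=60, length=150, seed=3)
        pwm = PWM("m", rng.integers(0, 12, size=(7, 4)).astype(float))
        ps = []
        for trial in range(60):
            idx = rng.choice(60, size=8, replace=False)
            targets = [bg.sequences[i] for i in idx]
            ps.append(enrichment_p(pwm, targets, bg, n_draws=100, seed=rng))
        assert abs(np.mean(ps) - 0.5) < 0.12


class TestScoreSeriesAndRanking:
    def _series(self, motif_id, raws, ps):
        return MotifScoreSeries(
            motif_id, "C1", np.array([0.0, 1.0, 2.0, 4.0]), np.array(raws), np.array(ps)
        )

    def test_planted_motif_rises_and_is_retained(self, rng):
        bg = uniform_bg(n=40, length=200, seed=9)
        consensus = "ACGTTGCA"
        pwm = PWM(
            "planted",
            np.array([[18.0 if b == c else 0.5 for b in "ACGT"] for c in consensus]),
        )
        def seqs_with(n_inst):
            out = []
            for _ in range(10):
                s = list("".join(rng.choice(list("ACGT"), size=150)))
                for k in range(n_inst):
                    pos = 10 + 30 * k
                    s[pos : pos + 8] = consensus
                out.append("".join(s))
            return out

        seqs_by_time = {0.0: seqs_with(0), 1.0: seqs_with(0),
                        2.0: seqs_with(2), 4.0: seqs_with(3)}
        series = score_series(pwm, seqs_by_time, bg, n_draws=200, seed=1)
        assert series.retained
        assert series.raw_scores[2] > series.raw_scores[0]
        assert series.raw_scores[3] > series.raw_scores[1]

    def test_absent_motif_not_retained(self, rng):
        bg = uniform_bg(n=40, length=200, seed=10)
        pwm = PWM("absent", np.array([[18.0, 0.5, 0.5, 0.5]] * 8))
        # targets drawn from the same base composition as the background:
        # the motif occurs nowhere at above-chance density
        seqs_by_time = {
            t: ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(8)]
            for t in (0.0, 1.0, 2.0, 4.0)
        }
        series = score_series(pwm, seqs_by_time, bg, n_draws=200, seed=2)
        assert not series.retained

    def test_shuffled_pwm_scores_below_planted(self, rng):
        bg = uniform_bg(n=30, length=200, seed=11)
        consensus = "AACCGGTT"
        counts = np.array([[18.0 if b == c else 0.5 for b in "ACGT"] for c in consensus])
        planted = PWM("planted", counts)
        shuffled = PWM("shuffled", counts[rng.permutation(8)])
        seqs = []
        for _ in range(10):
            s = list("".join(rng.choice(list("ACGT"), size=120)))
            s[20:28] = consensus
            s[60:68] = consensus
            seqs.append("".join(s))
        assert raw_score(planted, seqs, bg) > raw_score(shuffled, seqs, bg)

    def test_score_range_ranking(self):
        a = self._series("A", [0.0, 1.0, 2.0, 3.0], [0.001] * 4)
        b = self._series("B", [1.0, 1.5, 2.0, 2.0], [0.001] * 4)
        c = self._series("C", [1.0, 1.0, 1.0, 1.0], [0.001] * 4)
        ranked = rank_motifs([b, c, a], method="score_range")
        assert [s.motif_id for s, _ in ranked] == ["A", "B", "C"]
        assert ranked[0][1] == pytest.approx(3.0)
        assert ranked[-1][1] == pytest.approx(0.0)  # constant series ranks last

    def test_unretained_series_excluded(self):
        a = self._series("A", [0, 1, 2, 3], [0.5] * 4)
        assert rank_motifs([a]) == []

    def test_unknown_method_rejected(self):
        a = self._series("A", [0, 1, 2, 3], [0.001] * 4)
        with pytest.raises(ValueError):
            rank_motifs([a], method="bogus")

    def test_empty_time_point_recorded_as_undefined(self, rng):
        bg = uniform_bg(n=10, length=100, seed=12)
        pwm = PWM("m", rng.integers(0, 12, size=(5, 4)).astype(float))
        seqs_by_time = {0.0: [], 1.0: ["ACGTACGTAC"], 2.0: ["ACGTACGTAC"], 4.0: ["ACGTACGTAC"]}
        series = score_series(pwm, seqs_by_time, bg, n_draws=50, seed=0)
        assert np.isnan(series.raw_scores[0]) and np.isnan(series.p_values[0])
        assert np.isfinite(series.raw_scores[1:]).all()
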