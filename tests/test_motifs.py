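"""PWM scoring/scanning and motif-level filters."""

import math

import numpy as np
import pandas as pd
import pytest

from pioneerscan.intervals import IntervalSet
from pioneerscan.motifs import (
    PSEUDOCOUNT,
    PWM,
    classify_cpg_core,
    extract_words,
    mappability_filter,
    matched_control_sample,
    no_signal_motifs,
    reverse_complement,
    scan_genome,
    score_sequence,
)
from pioneerscan.simulate import surrogate_pu1_pwm
from pioneerscan.tracks import SignalTrack


def uniform_pwm(width=4):
    return PWM("uni", np.full((width, 4), 0.25))


def log_ratio(p, b=0.25):
    """Expected per-position contribution including the pseudocount."""
    pp = (p + PSEUDOCOUNT) / (1 + 4 * PSEUDOCOUNT)
    bb = (b + PSEUDOCOUNT) / (1 + 4 * PSEUDOCOUNT)
    return math.log(pp / bb)


class TestScoreSequence:
    def test_uniform_pwm_scores_zero(self):
        assert score_sequence(uniform_pwm(), "ACGT") == pytest.approx(0.0)

    def test_sum_of_per_position_log_ratios(self):
        probs = np.array(
            [[0.7, 0.1, 0.1, 0.1], [0.01, 0.01, 0.97, 0.01], [0.25] * 4, [0.25] * 4]
        )
        pwm = PWM("m", probs)
        expected = log_ratio(0.7) + log_ratio(0.97)  # uniform columns give 0
        assert score_sequence(pwm, "AGAA") == pytest.approx(expected)
        assert expected == pytest.approx(2.385, abs=0.03)

    def test_brute_force_max_is_consensus(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(4), size=4)
        pwm = PWM("m", probs)
        best = max(
            score_sequence(pwm, a + b + c + d)
            for a in "ACGT" for b in "ACGT" for c in "ACGT" for d in "ACGT"
        )
        assert best == pytest.approx(score_sequence(pwm, pwm.consensus))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_sequence(uniform_pwm(), "ACGTA")

    def test_n_scores_as_column_minimum(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        pwm = PWM("m", probs)
        per_n = pwm.log_odds[0, 4]
        assert per_n == pytest.approx(pwm.log_odds[0, :4].min())
        assert score_sequence(pwm, "NAAA") == pytest.approx(
            3 * log_ratio(0.97) + per_n
        )

    def test_strand_symmetry(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM("m", probs)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=6))
            assert score_sequence(pwm, seq) == pytest.approx(
                score_sequence(pwm.reverse_complement(), reverse_complement(seq)),
                abs=1e-12,
            )


class TestScanGenome:
    def test_planted_consensus_found(self):
        pwm = surrogate_pu1_pwm()
        genome = {"chrA": "T" * 500 + pwm.consensus + "T" * 500}
        matches = scan_genome(pwm, genome)
        plus = matches.df[matches.df["strand"] == "+"]
        assert (500, 512) in set(zip(plus["start"], plus["end"]))

    def test_reverse_complement_found_on_minus_strand(self):
        pwm = surrogate_pu1_pwm()
        genome = {"chrA": "T" * 500 + reverse_complement(pwm.consensus) + "T" * 500}
        matches = scan_genome(pwm, genome)
        minus = matches.df[matches.df["strand"] == "-"]
        row = minus[minus["start"] == 500]
        assert len(row) == 1
        assert row["score"].iloc[0] == pytest.approx(pwm.max_score)

    def test_equals_exhaustive_oracle(self, random_genome):
        genome = random_genome(length=10_000, seed=3)
        rng = np.random.default_rng(11)
        pwm = PWM("m", rng.dirichlet(np.full(4, 0.5), size=4), threshold=2.0)
        matches = scan_genome(pwm, genome)
        got = {(r.start, r.strand): r.score for r in matches.df.itertuples()}
        seq = genome["chrA"]
        expected = {}
        rc = pwm.reverse_complement()
        for i in range(len(seq) - pwm.width + 1):
            window = seq[i : i + pwm.width]
            s_plus = score_sequence(pwm, window)
            if s_plus >= pwm.threshold:
                expected[(i, "+")] = s_plus
            s_minus = score_sequence(rc, window)
            if s_minus >= pwm.threshold:
                expected[(i, "-")] = s_minus
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)


class TestPwmFile:
    def test_round_trip(self, tmp_path):
        pwm = surrogate_pu1_pwm()
        path = tmp_path / "m.pwm"
        pwm.write(str(path))
        back = PWM.read(str(path))
        assert back.name == pwm.name
        assert back.core_offset == pwm.core_offset
        assert back.threshold == pytest.approx(pwm.threshold)
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-5)


class TestMappabilityFilter:
    def make_matches(self, *starts):
        return IntervalSet.from_records(
            [("chrA", s, s + 12, "m", 1.0, "+") for s in starts],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )

    def test_fully_mappable_kept(self, flat_track):
        m = self.make_matches(5000)
        out = mappability_filter(m, flat_track, IntervalSet.empty())
        assert len(out) == 1

    def test_single_base_blacklist_overlap_removes(self, flat_track):
        m = self.make_matches(5000)  # 200-bp region = [4906, 5106)
        bl = IntervalSet.from_records([("chrA", 5105, 5200)])
        assert len(mappability_filter(m, flat_track, bl)) == 0
        bl2 = IntervalSet.from_records([("chrA", 5106, 5200)])
        assert len(mappability_filter(m, flat_track, bl2)) == 1

    def test_low_mappability_removed(self):
        arr = np.ones(10_000)
        arr[4900:5100] = 0.5
        track = SignalTrack({"chrA": arr})
        m = self.make_matches(5000, 8000)
        out = mappability_filter(m, track, IntervalSet.empty())
        assert out.df["start"].tolist() == [8000]

    def test_equals_manual_two_stage_filter(self, rng):
        arr = rng.random(10_000)
        track = SignalTrack({"chrA": arr})
        bl = IntervalSet.from_records([("chrA", 3000, 3200), ("chrA", 7000, 7050)])
        m = self.make_matches(*rng.integers(200, 9800, size=40).tolist())
        out = mappability_filter(m, track, bl)
        kept = []
        for r in m.df.itertuples(index=False):
            c = (r.start + r.end) // 2
            lo, hi = c - 100, c + 100
            if bl.coverage_array("chrA", 10_000)[lo:hi].any():
                continue
            if arr[lo:hi].mean() >= 0.8:
                kept.append(r.start)
        assert out.df["start"].tolist() == sorted(kept)


class TestNoSignal:
    def make(self, *starts):
        return IntervalSet.from_records(
            [("chrA", s, s + 12, "m", 0.0, "+") for s in starts],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )

    def track_with_window_count(self, count, center=5006):
        arr = np.zeros(10_000)
        arr[center] = count
        return SignalTrack({"chrA": arr}, library_size=1e7)  # norm factor 1

    def test_boundary_value_is_no_signal(self):
        m = self.make(5000)
        tracks = [self.track_with_window_count(c) for c in (0.0, 1.2, 3.0)]
        assert no_signal_motifs(m, tracks).tolist() == [True]

    def test_above_boundary_in_any_sample_removes(self):
        m = self.make(5000)
        tracks = [self.track_with_window_count(0.0), self.track_with_window_count(3.2)]
        assert no_signal_motifs(m, tracks).tolist() == [False]

    def test_zero_coverage_all_no_signal(self):
        m = self.make(100, 5000, 9000)
        track = SignalTrack({"chrA": np.zeros(10_000)}, library_size=1e7)
        assert no_signal_motifs(m, [track]).all()

    def test_monotone_in_samples(self, rng):
        m = self.make(*range(500, 9500, 500))
        tracks = [
            SignalTrack({"chrA": rng.poisson(0.01, 10_000).astype(float)}, library_size=1e7)
            for _ in range(3)
        ]
        prev = no_signal_motifs(m, tracks[:1])
        for k in (2, 3):
            cur = no_signal_motifs(m, tracks[:k])
            assert (cur <= prev).all()  # adding samples can only clear flags
            prev = cur


class TestCpgCore:
    def build(self, words, gap=1000):
        """Genome with the given motif words planted on the plus strand."""
        genome = ["T" * 500]
        rows = []
        pos = 500
        for w in words:
            rows.append(("chrA", pos, pos + len(w), "m", 0.0, "+"))
            genome.append(w)
            genome.append("T" * gap)
            pos += len(w) + gap
        return {"chrA": "".join(genome)}, IntervalSet.from_records(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    def test_cggaa_flagged_tggaa_not(self):
        genome, m = self.build(["AAAGCGGAAGTG", "AAAGTGGAAGTG"])
        out = classify_cpg_core(m, genome, core_offset=5)
        assert out["cpg_core"].tolist() == [True, False]
        assert out["meth_set"].all()

    def test_minus_strand_uses_sense_word(self):
        word = "AAAGCGGAAGTG"
        genome = {"chrA": "T" * 500 + reverse_complement(word) + "T" * 500}
        m = IntervalSet.from_records(
            [("chrA", 500, 512, "m", 0.0, "-")],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        out = classify_cpg_core(m, genome, core_offset=5)
        assert out["cpg_core"].tolist() == [True]

    def test_neighbor_within_150bp_excluded_from_meth_set(self):
        genome, m = self.build(["AAAGCGGAAGTG", "AAAGAGGAAGTG"], gap=68)  # starts 80 apart
        out = classify_cpg_core(m, genome, core_offset=5)
        assert out["cpg_core"].tolist() == [True, False]
        assert out["meth_set"].tolist() == [False, False]

    def test_missing_core_offset_is_config_error(self):
        genome, m = self.build(["AAAGCGGAAGTG"])
        with pytest.raises(ValueError):
            classify_cpg_core(m, genome, core_offset=None)


class TestMatchedControls:
    def plant(self, words, start=500, gap=1000, chrom="chrA"):
        genome = ["T" * start]
        rows = []
        pos = start
        for w in words:
            rows.append((chrom, pos, pos + len(w), "m", 0.0, "+"))
            genome.append(w + "T" * gap)
            pos += len(w) + gap
        return "".join(genome), rows

    def setup_sets(self, target_words, pool_words):
        g1, rows1 = self.plant(target_words)
        g2, rows2 = self.plant(pool_words, chrom="chrB")
        genome = {"chrA": g1, "chrB": g2}
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        return (
            genome,
            IntervalSet.from_records(rows1, columns=cols),
            IntervalSet.from_records(rows2, columns=cols),
        )

    def test_multiset_equality_when_pool_suffices(self):
        w1, w2 = "AAAGAGGAAGTG", "CCCGAGGAACCC"
        genome, targets, pool = self.setup_sets(
            [w1, w1, w2], [w1] * 5 + [w2] * 3
        )
        controls, shortfall = matched_control_sample(targets, pool, genome, seed=0)
        assert shortfall == {}
        got = extract_words(controls, genome).value_counts().to_dict()
        assert got == {w1: 2, w2: 1}

    def test_shortfall_reported_exactly(self):
        w1 = "AAAGAGGAAGTG"
        genome, targets, pool = self.setup_sets([w1, w1], [w1])
        controls, shortfall = matched_control_sample(targets, pool, genome, seed=0)
        assert len(controls) == 1
        assert shortfall == {w1: 1}

    def test_seed_determinism_and_word_invariance(self):
        w1 = "AAAGAGGAAGTG"
        genome, targets, pool = self.setup_sets([w1, w1], [w1] * 6)
        c1, _ = matched_control_sample(targets, pool, genome, seed=3)
        c2, _ = matched_control_sample(targets, pool, genome, seed=3)
        c3, _ = matched_control_sample(targets, pool, genome, seed=4)
        assert c1.df.equals(c2.df)
        assert extract_words(c3, genome).value_counts().to_dict() == {w1: 2}
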