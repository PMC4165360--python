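"""PFM parsing, information content, PWM scoring and the overlap rule."""

import math

import numpy as np
import pytest

from zingerscan import motifs
from zingerscan.motifs import (
    MotifFormatError,
    PFM,
    information_content,
    parse_jaspar_pfm,
    pfm_to_pwm,
    relative_score,
    scan_sequence,
    shuffle_pfm,
    write_jaspar_pfm,
)

from conftest import random_sequence


class TestParsing:
    def test_decorated_and_bare_dialects_agree(self):
        decorated = ">MA0001 test\nA [ 5 0 2 1 ]\nC [ 1 9 0 0 ]\nG [ 2 0 6 1 ]\nT [ 2 1 2 8 ]\n"
        bare = ">MA0001 test\n5 0 2 1\n1 9 0 0\n2 0 6 1\n2 1 2 8\n"
        a, b = parse_jaspar_pfm(decorated), parse_jaspar_pfm(bare)
        assert a.id == b.id == "MA0001"
        assert a.name == b.name == "test"
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_uniform_counts(self):
        pfm = parse_jaspar_pfm(">X\n5 5 5 5\n5 5 5 5\n5 5 5 5\n5 5 5 5\n")
        assert pfm.width == 4
        np.testing.assert_array_equal(pfm.counts, np.full((4, 4), 5.0))

    def test_rows_reordered_by_label(self):
        text = ">X\nT [ 1 2 ]\nG [ 3 4 ]\nC [ 5 6 ]\nA [ 7 8 ]\n"
        # 2 columns < 4 minimum; widen
        text = ">X\nT [ 1 2 9 9 ]\nG [ 3 4 9 9 ]\nC [ 5 6 9 9 ]\nA [ 7 8 9 9 ]\n"
        pfm = parse_jaspar_pfm(text)
        assert pfm.counts[0, 0] == 7  # A row first regardless of input order
        assert pfm.counts[3, 0] == 1

    @pytest.mark.parametrize(
        "bad",
        [
            ">X\n1 2 3 4\n1 2 3 4\n1 2 3 4\n",  # 3 rows
            ">X\n1 2 3 4\n1 2 3\n1 2 3 4\n1 2 3 4\n",  # ragged
            "no header\n1 2 3 4\n" * 4,
        ],
    )
    def test_malformed_records_raise(self, bad):
        with pytest.raises(MotifFormatError):
            parse_jaspar_pfm(bad)

    def test_round_trip_random_pfms(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=(4, int(rng.integers(4, 20)))).astype(float)
            counts[rng.integers(4), :] += 1  # keep column sums positive
            pfm = PFM("MA0000", "rt", counts)
            for decorated in (True, False):
                again = parse_jaspar_pfm(write_jaspar_pfm(pfm, decorated))
                np.testing.assert_array_equal(again.counts, pfm.counts)


class TestInformationContent:
    def test_uniform_columns_are_zero_bits(self):
        pfm = PFM("u", "", np.full((4, 6), 2.5))
        assert information_content(pfm) == pytest.approx(0.0, abs=1e-12)

    def test_single_base_column_is_two_bits(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 10
        assert information_content(PFM("s", "", counts)) == pytest.approx(2.0)

    def test_mixed_column_matches_direct_entropy(self):
        counts = np.array([[6.0], [2.0], [1.0], [1.0]])
        freqs = [0.6, 0.2, 0.1, 0.1]
        expected = 2.0 + sum(f * math.log2(f) for f in freqs)
        assert information_content(PFM("m", "", counts)) == pytest.approx(expected)

    def test_invariant_under_column_permutation(self, zingers, rng):
        pfm = zingers["CTCF_like"]
        shuffled = shuffle_pfm(pfm, rng=rng)
        assert information_content(shuffled) == pytest.approx(information_content(pfm))


class TestPwm:
    def test_uniform_column_gives_equal_weights(self):
        counts = np.full((4, 4), 10.0)
        counts[:, 0] = [30, 4, 3, 3]  # one informative column keeps the PWM non-degenerate
        pwm = pfm_to_pwm(PFM("u", "", counts))
        for j in range(1, 4):
            assert np.allclose(pwm.weights[:, j], pwm.weights[0, j])

    def test_log_odds_sign(self):
        counts = np.array([[0.0], [0.0], [0.0], [4.0]])
        pwm = pfm_to_pwm(PFM("t", "", counts))
        assert pwm.weights[3, 0] > 0 > pwm.weights[0, 0]

    def test_sqrt_n_pseudocount_formula(self):
        counts = np.array([[97.0], [1.0], [1.0], [1.0]])
        pwm = pfm_to_pwm(PFM("f", "", counts))
        n = 100.0
        for b, c in enumerate([97.0, 1.0, 1.0, 1.0]):
            expected = math.log2((c + 0.25 * math.sqrt(n)) / (n + math.sqrt(n)) / 0.25)
            assert pwm.weights[b, 0] == pytest.approx(expected, abs=1e-12)

    def test_relative_score_extremes(self, jun_pwm):
        argmax = "".join("ACGT"[i] for i in jun_pwm.weights.argmax(axis=0))
        argmin = "".join("ACGT"[i] for i in jun_pwm.weights.argmin(axis=0))
        assert relative_score(jun_pwm, argmax) == pytest.approx(100.0)
        assert relative_score(jun_pwm, argmin) == pytest.approx(0.0)

    def test_relative_score_matches_hand_summation(self, jun_pwm, rng):
        word = random_sequence(rng, jun_pwm.width)
        raw = sum(
            jun_pwm.weights["ACGT".index(ch), j] for j, ch in enumerate(word)
        )
        expected = 100 * (raw - jun_pwm.min_score) / (jun_pwm.max_score - jun_pwm.min_score)
        assert relative_score(jun_pwm, word) == pytest.approx(expected)

    def test_relative_score_monotone_toward_column_max(self, jun_pwm, rng):
        for _ in range(20):
            word = list(random_sequence(rng, jun_pwm.width))
            j = int(rng.integers(jun_pwm.width))
            before = relative_score(jun_pwm, "".join(word))
            word[j] = "ACGT"[int(jun_pwm.weights[:, j].argmax())]
            assert relative_score(jun_pwm, "".join(word)) >= before - 1e-9

    def test_bad_word_rejected(self, jun_pwm):
        with pytest.raises(ValueError):
            relative_score(jun_pwm, "TGAXTCA")
        with pytest.raises(ValueError):
            relative_score(jun_pwm, "TGA")


def brute_force_scan(pwm, seq, threshold, overlap_fraction=0.2):
    """Exhaustive-window oracle: enumerate, sort, greedily filter."""
    L = pwm.width
    comp = str.maketrans("ACGTN", "TGCAN")
    cands = []
    for start in range(len(seq) - L + 1):
        word = seq[start : start + L]
        for strand in "+-":
            w = word if strand == "+" else word.translate(comp)[::-1]
            s = relative_score(pwm, w)
            if s >= threshold:
                cands.append((start, strand, s))
    cands.sort(key=lambda c: (-c[2], c[0], c[1]))
    kept = []
    max_olap = int(L * overlap_fraction)
    for start, strand, s in cands:
        if all(L - abs(start - k[0]) <= max_olap for k in kept):
            kept.append((start, strand, s))
    return sorted((k[0], k[1]) for k in kept), sorted(k[2] for k in kept)


class TestScanning:
    def test_empty_and_short_sequences(self, jun_pwm):
        assert scan_sequence(jun_pwm, "", 70) == []
        assert scan_sequence(jun_pwm, "ACGT", 70) == []

    def test_seven_bp_matrix_allows_one_bp_overlap(self, jun_pwm):
        # consensus TGACTCA at starts 0 and 6 overlap by exactly 1 bp
        hits = scan_sequence(jun_pwm, "TGACTCTGACTCA", 75)
        starts = sorted(h.start for h in hits)
        assert starts == [0, 6]
        # starts 0 and 5 would overlap by 2 bp: the weaker one is dropped
        hits = scan_sequence(jun_pwm, "TGACTTGACTCA", 75)
        assert len(hits) == 1 and hits[0].start == 5

    def test_retained_hits_never_exceed_overlap_bound(self, jun_pwm, rng):
        max_olap = int(jun_pwm.width / 5)
        for _ in range(10):
            seq = random_sequence(rng, 300)
            hits = scan_sequence(jun_pwm, seq, 60)
            for i, a in enumerate(hits):
                for b in hits[i + 1 :]:
                    assert jun_pwm.width - abs(a.start - b.start) <= max_olap

    def test_matches_brute_force_oracle(self, zingers, rng):
        pwm = motifs.pfm_to_pwm(zingers["THAP11_like"])
        for _ in range(25):
            seq = random_sequence(rng, 150)
            hits = scan_sequence(pwm, seq, 70.5)
            got = sorted((h.start, h.strand) for h in hits)
            got_scores = sorted(h.rel_score for h in hits)
            exp, exp_scores = brute_force_scan(pwm, seq, 70.5)
            assert got == exp
            np.testing.assert_allclose(got_scores, exp_scores, atol=1e-9)

    def test_n_windows_score_column_minimum(self, jun_pwm):
        full = relative_score(jun_pwm, "TGACTCA")
        with_n = relative_score(jun_pwm, "TGANTCA")
        worst_mid = min(
            relative_score(jun_pwm, f"TGA{b}TCA") for b in "ACGT"
        )
        assert with_n == pytest.approx(worst_mid)
        assert with_n < full


class TestShuffling:
    def test_column_multiset_and_row_totals_preserved(self, zingers, rng):
        pfm = zingers["ETS_like"]
        shuffled = shuffle_pfm(pfm, rng=rng)
        assert sorted(map(tuple, pfm.counts.T.tolist())) == sorted(
            map(tuple, shuffled.counts.T.tolist())
        )
        np.testing.assert_allclose(pfm.counts.sum(axis=1), shuffled.counts.sum(axis=1))

    def test_edge_columns_fixed(self, zingers, rng):
        pfm = zingers["CTCF_like"]  # width 19 -> 3 fixed columns per side
        shuffled = shuffle_pfm(pfm, rng=rng)
        np.testing.assert_array_equal(shuffled.counts[:, :3], pfm.counts[:, :3])
        np.testing.assert_array_equal(shuffled.counts[:, -3:], pfm.counts[:, -3:])

    def test_single_internal_column_is_identity(self, rng):
        counts = np.arange(20, dtype=float).reshape(4, 5) + 1
        pfm = PFM("small", "", counts)
        shuffled = shuffle_pfm(pfm, fixed_edge_columns=2, rng=rng)
        np.testing.assert_array_equal(shuffled.counts, pfm.counts)

    def test_width_too_small_raises(self):
        counts = np.ones((4, 4))
        with pytest.raises(ValueError):
            shuffle_pfm(PFM("tiny", "", counts), fixed_edge_columns=2)

    def test_all_internal_arrangements_reachable(self):
        counts = np.arange(28, dtype=float).reshape(4, 7) + 1
        pfm = PFM("seven", "", counts)
        seen = set()
        for seed in range(200):
            shuffled = shuffle_pfm(pfm, fixed_edge_columns=2, rng=seed)
            seen.add(tuple(map(tuple, shuffled.counts[:, 2:5].T.tolist())))
        assert len(seen) == 6  # all 3! permutations of the internal columns
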