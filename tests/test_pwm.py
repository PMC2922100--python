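"""PWM construction, similarity scoring, scanning and threshold calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crmscan as c
from conftest import toy_pwm
import oracles


class TestInformationVector:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((10, 0, 0, 0), 100.0),  # fully conserved
            ((5, 5, 5, 5), 0.0),  # uniform
            ((5, 5, 0, 0), 50.0),  # two equiprobable bases: (100/ln4)(ln4-ln2)
        ],
    )
    def test_closed_form_rows(self, row, expected):
        assert c.information_vector([row])[0] == pytest.approx(expected, abs=1e-9)

    def test_exactly_100_only_for_single_base_rows(self):
        ci = c.information_vector([(10, 0, 0, 0), (999, 1, 0, 0), (1, 0, 0, 0)])
        assert ci[0] == 100.0 and ci[2] == 100.0
        assert ci[1] < 100.0

    def test_matches_formula_oracle_on_random_rows(self):
        rng = np.random.default_rng(42)
        rows = rng.integers(0, 30, size=(50, 4))
        rows[rows.sum(axis=1) == 0, 0] = 1
        got = c.information_vector(rows)
        want = [oracles.info_value(r) for r in rows]
        assert got == pytest.approx(want, abs=1e-9)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            c.information_vector([(0, 0, 0, 0)])


class TestCorePositions:
    def test_forced_when_length_equals_core(self):
        assert list(c.core_positions([10, 20, 30, 40])) == [0, 1, 2, 3]

    def test_picks_max_sum_window(self):
        info = [10, 90, 90, 90, 90, 10]
        # windows: 0..3 -> 280, 1..4 -> 360, 2..5 -> 280
        assert list(c.core_positions(info)) == [1, 2, 3, 4]

    def test_tie_breaks_to_smallest_start(self):
        assert list(c.core_positions([50] * 7)) == [0, 1, 2, 3]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            c.core_positions([1, 2, 3])


class TestSimilarityScores:
    # rows (8,0,0,0), (4,4,0,0), (0,0,8,0): Ci = 100, 50, 100
    counts3 = [(8, 0, 0, 0), (4, 4, 0, 0), (0, 0, 8, 0)]

    def test_consensus_scores_one(self):
        pwm = toy_pwm(self.counts3, pseudocount=0.0)
        for s in ("AAG", "ACG"):  # both bases tie at the middle position
            assert pwm.matrix_similarity(s) == pytest.approx(1.0)

    def test_hand_value_from_formula(self):
        pwm = toy_pwm(self.counts3, pseudocount=0.0)
        # "ACT": 100*1 + 50*0.5 + 100*0 over 100 + 25 + 100
        assert pwm.matrix_similarity("ACT") == pytest.approx(125 / 225)
        assert pwm.matrix_similarity("ACT") == pytest.approx(
            oracles.score_window(self.counts3, "ACT", 0.0)
        )

    def test_single_substitution_scores_below_one(self, library):
        pwm = library.get("NEUR_1")
        s = list(pwm.consensus)
        for pos in range(len(s)):
            if pwm.info[pos] == 0:
                continue  # uninformative position: substitution is free
            for b in "ACGT":
                if b == s[pos]:
                    continue
                mutated = "".join(s[:pos]) + b + "".join(s[pos + 1 :])
                assert pwm.matrix_similarity(mutated) < 1.0

    def test_core_similarity_equals_matrix_similarity_for_L4(self):
        pwm = toy_pwm([(9, 1, 0, 0), (0, 8, 2, 0), (1, 1, 7, 1), (0, 0, 0, 10)])
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), 4))
            assert pwm.core_similarity(s) == pytest.approx(pwm.matrix_similarity(s))

    def test_core_match_with_flank_mismatch(self, library):
        pwm = library.get("HNF1_1")
        s = list(pwm.consensus)
        noncore = [i for i in range(len(s)) if i not in set(pwm.core) and pwm.info[i] > 0]
        i = noncore[0]
        s[i] = next(b for b in "ACGT" if b != s[i])
        mutated = "".join(s)
        assert pwm.core_similarity(mutated) == pytest.approx(1.0)
        assert pwm.matrix_similarity(mutated) < 1.0

    def test_zero_frequency_core_mismatch_contributes_zero(self):
        counts = [(8, 0, 0, 0)] * 4
        pwm = toy_pwm(counts, pseudocount=0.0)
        assert pwm.core_similarity("CAAA") == pytest.approx(0.75)

    def test_exhaustive_consensus_iff_score_one(self):
        """matrix_similarity == 1 exactly on argmax-base windows (all 4^L)."""
        counts = [(12, 4, 2, 2), (0, 18, 1, 1), (5, 5, 5, 5), (1, 1, 16, 2), (9, 9, 1, 1)]
        pwm = toy_pwm(counts)
        for bases in itertools.product("ACGT", repeat=len(counts)):
            s = "".join(bases)
            score = pwm.matrix_similarity(s)
            assert 0 < score <= 1 + 1e-12
            assert (score == pytest.approx(1.0)) == pwm.is_consensus(s)

    def test_length_mismatch_rejected(self, library):
        with pytest.raises(ValueError):
            library.get("NEUR_1").matrix_similarity("ACGT")

    def test_window_with_n_scores_zero(self):
        pwm = toy_pwm([(8, 0, 0, 0)] * 5)
        assert pwm.matrix_similarity("AANAA") == 0.0


class TestScan:
    def test_planted_consensus_recovered_at_offset(self, library):
        pwm = library.get("PDX1_1")
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        seq = seq[:1200] + pwm.consensus + seq[1200 + len(pwm) :]
        hits = c.scan_sequence(c.PWMLibrary([pwm]), seq, thresholds=0.99)
        exact = [h for h in hits if h.start == 1200 and h.strand == "+"]
        assert exact and exact[0].matrix_similarity == pytest.approx(1.0)
        assert exact[0].core_similarity == pytest.approx(1.0)
        assert exact[0].position_rel_tss == 1200 - 4500

    def test_strand_mirror_symmetry(self, library):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        sub = c.PWMLibrary([library.get("NEUR_1"), library.get("LEFF_1")])
        fwd = c.scan_sequence(sub, seq, thresholds=0.7)
        rev = c.scan_sequence(sub, c.reverse_complement(seq), thresholds=0.7)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - h.start - h.width, h.matrix, flip[h.strand],
             round(h.core_similarity, 9), round(h.matrix_similarity, 9))
            for h in rev
        )
        assert mirrored == sorted(
            (h.start, h.matrix, h.strand,
             round(h.core_similarity, 9), round(h.matrix_similarity, 9))
            for h in fwd
        )

    def test_matches_naive_rescoring_oracle(self):
        counts = [(14, 2, 2, 2), (2, 14, 2, 2), (2, 2, 14, 2), (5, 5, 5, 5), (14, 2, 2, 2), (2, 2, 2, 14)]
        pwm = toy_pwm(counts, name="m6", family="F6")
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 400))
        hits = c.scan_sequence(c.PWMLibrary([pwm]), seq, core_cut=0.75, thresholds=0.8)
        got = sorted(
            (h.start, h.strand, round(h.core_similarity, 9), round(h.matrix_similarity, 9))
            for h in hits
        )
        want = [
            (s, strand, round(cs, 9), round(ms, 9))
            for s, strand, cs, ms in oracles.naive_scan(
                counts, seq, c.pwm.DEFAULT_PSEUDOCOUNT, 0.75, 0.8
            )
        ]
        assert got == want

    def test_all_n_sequence_yields_no_hits(self, library):
        assert c.scan_sequence(library, "N" * 100, thresholds=0.0) == []

    def test_raising_threshold_never_adds_hits(self, library):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        lo = c.scan_sequence(library, seq, thresholds=0.75)
        hi = c.scan_sequence(library, seq, thresholds=0.85)
        lo_keys = {(h.start, h.matrix, h.strand) for h in lo}
        hi_keys = {(h.start, h.matrix, h.strand) for h in hi}
        assert hi_keys <= lo_keys

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            c.scan_sequence(c.PWMLibrary([]), "ACGT" * 100)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=30, max_size=120), st.integers(0, 2**16))
    def test_scores_bounded_on_arbitrary_sequences(self, seq, seed):
        pwm = toy_pwm([(12, 4, 2, 2), (0, 18, 1, 1), (1, 1, 16, 2), (9, 9, 1, 1), (2, 2, 2, 14)])
        hits = c.scan_sequence(c.PWMLibrary([pwm]), seq, core_cut=0.0, thresholds=0.0)
        for h in hits:
            assert 0 < h.core_similarity <= 1 + 1e-12
            assert 0 < h.matrix_similarity <= 1 + 1e-12


class TestCalibration:
    def test_infinite_target_rate_gives_minimum_grid_value(self, library):
        res = c.calibrate_optimized_threshold(
            library.get("NEUR_1"), target_rate=float("inf"), seed=2
        )
        assert res.threshold == pytest.approx(c.pwm.THRESHOLD_GRID[0])
        assert not res.unreachable

    def test_deterministic_given_seed(self, library):
        a = c.calibrate_optimized_threshold(library.get("HNF6_1"), seed=9)
        b = c.calibrate_optimized_threshold(library.get("HNF6_1"), seed=9)
        assert a == b

    def test_sharper_matrix_needs_no_higher_threshold(self):
        """A more informative matrix is rarer on background, so its
        rate-calibrated threshold is <= a flatter matrix's at the same rate."""
        sharp = toy_pwm([(20, 0, 0, 0), (0, 20, 0, 0)] * 5, name="sharp")
        flat = toy_pwm([(11, 3, 3, 3), (3, 11, 3, 3)] * 5, name="flat")
        for seed in (1, 2, 3):
            t_sharp = c.calibrate_optimized_threshold(sharp, seed=seed).threshold
            t_flat = c.calibrate_optimized_threshold(flat, seed=seed).threshold
            assert t_sharp <= t_flat

    def test_unreachable_rate_flagged(self):
        # a 6-mer of moderate information matches background too often for a
        # target of 0 hits per 10 kb even at threshold 1.0
        pwm = toy_pwm([(11, 3, 3, 3)] * 6, name="weak")
        res = c.calibrate_optimized_threshold(pwm, target_rate=0.0, seed=4)
        assert res.unreachable and res.threshold == 1.0

    def test_background_too_short_rejected(self, library):
        with pytest.raises(ValueError):
            c.calibrate_optimized_threshold(library.get("NEUR_1"), background_length=500)


class TestPFMSerialization:
    def test_round_trip(self, library, tmp_path):
        path = tmp_path / "lib.pfm"
        library.write(path)
        back = c.PWMLibrary.read(path)
        assert [m.name for m in back] == [m.name for m in library]
        for a, b in zip(library, back):
            assert a.family == b.family
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_four_column_blocks_accepted(self):
        text = ">M1 FAM\n8 0 0 0\n4 4 0 0\n0 0 8 0\n"
        lib = c.PWMLibrary.from_pfm_text(text)
        assert lib.get("M1").consensus in ("AAG", "ACG")

    def test_duplicate_names_rejected(self, library):
        with pytest.raises(ValueError):
            c.PWMLibrary(list(library) + [library.get("NEUR_1")])
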