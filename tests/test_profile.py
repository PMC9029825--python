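import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrscan.io import ProteinRecord, ScoreTrack
from idrscan.profile import (
    DisorderThresholds,
    classify_band,
    disorder_rate,
    find_long_idrs,
    mean_disorder,
    residue_is_disordered,
    summarize_protein,
)


def track(scores, acc="T"):
    return ScoreTrack(acc, np.asarray(scores, dtype=float))


class TestResidueCall:
    def test_cutoff_is_inclusive(self, thresholds):
        assert residue_is_disordered(0.5, thresholds)
        assert not residue_is_disordered(0.4999, thresholds)

    def test_out_of_range_score_rejected(self, thresholds):
        with pytest.raises(ValueError):
            residue_is_disordered(1.5, thresholds)

    def test_counting_matches_bruteforce(self, rng, thresholds):
        scores = rng.uniform(0, 1, size=1000)
        n = sum(residue_is_disordered(s, thresholds) for s in scores)
        assert n == sum(1 for s in scores if s >= 0.5)


class TestRateAndMean:
    def test_half_disordered(self, thresholds):
        assert disorder_rate(track([0.6, 0.6, 0.4, 0.4]), thresholds) == 50.0

    def test_all_at_cutoff_is_fully_disordered(self, thresholds):
        assert disorder_rate(track([0.5] * 7), thresholds) == 100.0

    def test_rate_matches_counting_oracle(self, rng, thresholds):
        scores = rng.uniform(0, 1, size=73)
        expected = sum(1 for s in scores if s >= 0.5) * 100.0 / 73
        assert disorder_rate(track(scores), thresholds) == pytest.approx(expected)

    def test_mean_disorder(self, rng):
        assert mean_disorder(track([0.2, 0.8])) == pytest.approx(0.5)
        assert mean_disorder(track([0.3] * 17)) == pytest.approx(0.3)
        scores = rng.uniform(0, 1, size=211)
        assert mean_disorder(track(scores)) == pytest.approx(
            sum(scores) / 211, abs=1e-12
        )


class TestBands:
    @pytest.mark.parametrize(
        "rate, band",
        [(5, "OP"), (75, "MDP"), (10, "NOP"), (30, "PDP"), (70, "MDP"),
         (0, "OP"), (100, "MDP"), (29.999, "NOP")],
    )
    def test_lower_inclusive_convention(self, rate, band, thresholds):
        assert classify_band(rate, thresholds) == band

    @pytest.mark.parametrize(
        "rate, band", [(10, "OP"), (30, "NOP"), (70, "PDP"), (70.01, "MDP")]
    )
    def test_upper_inclusive_convention(self, rate, band):
        upper = DisorderThresholds(boundary_convention="upper")
        assert classify_band(rate, upper) == band

    def test_band_sweep_is_monotone_step_function(self, thresholds):
        order = {"OP": 0, "NOP": 1, "PDP": 2, "MDP": 3}
        levels = [order[classify_band(r / 2, thresholds)] for r in range(201)]
        assert levels == sorted(levels)
        # changes exactly at the three bounds
        assert sum(b - a for a, b in zip(levels, levels[1:])) == 3

    def test_out_of_range_rate_rejected(self, thresholds):
        with pytest.raises(ValueError):
            classify_band(101.0, thresholds)


def rle_segments(mask, min_len):
    """Independent run-length-encoding oracle (1-based inclusive)."""
    segments, start = [], None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                segments.append((start + 1, i))
            start = None
    return segments


class TestLongIDRs:
    def test_nineteen_consecutive_is_not_long(self, thresholds):
        scores = [0.1] * 5 + [0.9] * 19 + [0.1] * 5
        assert find_long_idrs(track(scores), thresholds) == []

    def test_twenty_consecutive_qualifies(self, thresholds):
        scores = [0.1] * 4 + [0.9] * 20 + [0.1] * 4
        (seg,) = find_long_idrs(track(scores), thresholds)
        assert (seg.start, seg.end, seg.length) == (5, 24, 20)

    def test_run_spanning_chain_end(self, thresholds):
        (seg,) = find_long_idrs(track([0.9] * 25), thresholds)
        assert (seg.start, seg.end) == (1, 25)

    def test_matches_rle_oracle_on_random_tracks(self, rng, thresholds):
        for _ in range(500):
            n = int(rng.integers(1, 120))
            scores = np.where(rng.random(n) < 0.5, 0.9, 0.1)
            got = [(s.start, s.end) for s in find_long_idrs(track(scores), thresholds)]
            assert got == rle_segments(scores >= 0.5, 20)

    @given(st.lists(st.booleans(), min_size=1, max_size=200), st.integers(1, 25))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_segments_maximal_disjoint_and_above_cutoff(self, flags, min_len):
        scores = np.where(flags, 0.8, 0.2)
        th = DisorderThresholds(min_idr_length=min_len)
        segs = find_long_idrs(track(scores), th)
        prev_end = 0
        for seg in segs:
            assert seg.length >= min_len
            assert seg.start > prev_end  # sorted and disjoint
            assert all(scores[seg.start - 1 : seg.end] >= 0.5)
            # maximality: neighbors below cutoff or chain ends
            assert seg.start == 1 or scores[seg.start - 2] < 0.5
            assert seg.end == len(scores) or scores[seg.end] < 0.5
            prev_end = seg.end


class TestSummary:
    def test_constructed_case(self, thresholds):
        record = ProteinRecord("P1", "", "A" * 100)
        scores = [0.9] * 80 + [0.1] * 20
        summary = summarize_protein(record, track(scores, "P1"), thresholds)
        assert summary.disorder_rate == 80.0
        assert summary.band == "MDP"
        assert [(s.start, s.end) for s in summary.long_idrs] == [(1, 80)]

    def test_fully_ordered_protein(self, thresholds):
        record = ProteinRecord("P2", "", "A" * 30)
        summary = summarize_protein(record, track([0.1] * 30, "P2"), thresholds)
        assert summary.disorder_rate == 0.0
        assert summary.band == "OP"
        assert summary.long_idrs == []

    def test_length_mismatch_names_accession(self, thresholds):
        with pytest.raises(ValueError, match="P3"):
            summarize_protein(
                ProteinRecord("P3", "", "AAA"), track([0.5, 0.5], "P3"), thresholds
            )

    def test_composes_individual_operations(self, rng, thresholds):
        for _ in range(25):
            n = int(rng.integers(1, 150))
            scores = rng.uniform(0, 1, size=n)
            t = track(scores, "PX")
            record = ProteinRecord("PX", "", "A" * n)
            s = summarize_protein(record, t, thresholds)
            assert s.disorder_rate == disorder_rate(t, thresholds)
            assert s.mean_disorder == mean_disorder(t)
            assert s.band == classify_band(s.disorder_rate, thresholds)
            assert s.long_idrs == find_long_idrs(t, thresholds)
            # IDR residues are a subset of disordered residues
            assert s.disorder_rate >= 100.0 * sum(
                seg.length for seg in s.long_idrs
            ) / n - 1e-9
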