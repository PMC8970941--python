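"""Normalized error distances, classification, distributions, rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wedm import (
    ScoredSegment,
    classify_segment,
    compute_ned,
    default_hit_threshold,
    frequency_distribution,
    mwed,
    mwtd,
    normalized_times,
    rates,
    wed_distribution,
)
from wedm.metrics import DistributionBin
from wedm.segmentation import Segment


class TestComputeNed:
    @pytest.mark.parametrize(
        "ecp, expected_signed, expected_ned",
        [
            (101, 0.0, 0.0),  # exactly on target
            (51, -0.5, 0.5),  # halfway into the left flank
            (201, 1.0, 1.0),  # at the segment end
            (1, -1.0, 1.0),  # at the segment start
            (151, 0.5, 0.5),
        ],
    )
    def test_worked_values(self, wide_segment, ecp, expected_signed,
                           expected_ned):
        signed, ned = compute_ned(wide_segment, ecp)
        assert signed == pytest.approx(expected_signed)
        assert ned == pytest.approx(expected_ned)

    def test_asymmetric_flanks_normalize_independently(self):
        seg = Segment(1, 100, 20)  # left flank 19, right flank 80
        assert compute_ned(seg, 10)[1] == pytest.approx(10 / 19)
        assert compute_ned(seg, 60)[1] == pytest.approx(40 / 80)

    def test_outside_segment_rejected(self, wide_segment):
        with pytest.raises(ValueError, match="not in segment"):
            compute_ned(wide_segment, 300)

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_ned(Segment(1, 10, 1), 5)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_ned_in_unit_interval_and_signed(self, data):
        start = data.draw(st.integers(1, 100))
        tcp = data.draw(st.integers(start + 1, start + 200))
        end = data.draw(st.integers(tcp + 1, tcp + 200))
        ecp = data.draw(st.integers(start, end))
        signed, ned = compute_ned(Segment(start, end, tcp), ecp)
        assert 0.0 <= ned <= 1.0
        assert abs(signed) == pytest.approx(ned)
        assert (signed < 0) == (ecp < tcp) or ned == 0


class TestClassify:
    def test_hit_within_radius(self, wide_segment):
        scored, n_red = classify_segment(wide_segment, [100], hd=2)
        assert scored.state == "hit"
        assert scored.contribution == 0.0
        assert n_red == 0

    def test_empty_is_miss_with_unit_contribution(self, wide_segment):
        scored, n_red = classify_segment(wide_segment, [], hd=2)
        assert scored.state == "miss"
        assert scored.ned == 1.0 and scored.signed_ned == 1.0
        assert n_red == 0

    def test_nearest_scores_rest_redundant(self, wide_segment):
        scored, n_red = classify_segment(wide_segment, [51, 150], hd=2)
        assert scored.state == "error"
        assert scored.ecp == 150  # nearer to target 101 than 51
        assert scored.ned == pytest.approx(0.49)
        assert n_red == 1

    def test_tie_breaks_to_smaller_position(self, wide_segment):
        scored, _ = classify_segment(wide_segment, [91, 111], hd=2)
        assert scored.ecp == 91

    def test_ecp_outside_segment_rejected(self, wide_segment):
        with pytest.raises(ValueError):
            classify_segment(wide_segment, [500], hd=2)

    def test_default_hit_threshold_scales_with_segment(self):
        assert default_hit_threshold(Segment(1, 201, 101)) == 1
        assert default_hit_threshold(Segment(1, 1000, 500)) == 5
        assert default_hit_threshold(Segment(1, 10, 5)) == 1  # floor of 1


def _scored(states_neds, seg=Segment(1, 201, 101)):
    out = []
    for state, ned in states_neds:
        signed = ned if state != "hit" else 0.0
        out.append(ScoredSegment(seg, None if state == "miss" else 101,
                                 state, abs(ned), signed))
    return out


class TestAggregates:
    def test_mwed_hit_miss_composition(self):
        scored = _scored([("hit", 0.0)] * 14 + [("miss", 1.0)] * 16)
        assert mwed(scored) == pytest.approx(16 / 30)

    def test_mwed_all_hits_zero(self):
        assert mwed(_scored([("hit", 0.0)] * 5)) == 0.0

    def test_mwed_uses_error_ned(self):
        scored = _scored([("hit", 0.0), ("error", 0.5), ("miss", 1.0)])
        assert mwed(scored) == pytest.approx(0.5)

    def test_mwtd_complement(self):
        assert mwtd(0.0586) == pytest.approx(0.9414)
        assert mwtd(0.0) == 1.0
        with pytest.raises(ValueError):
            mwtd(1.5)

    def test_mwed_monotone_in_detection_distance(self, wide_segment):
        """Moving the scoring eCP closer to the target never raises MWED."""
        prev = None
        for ecp in (201, 180, 150, 120, 103):
            scored, _ = classify_segment(wide_segment, [ecp], hd=1)
            value = mwed([scored])
            if prev is not None:
                assert value <= prev
            prev = value

    def test_rates_scored_events_sum_to_one(self):
        scored = _scored(
            [("hit", 0.0)] * 3 + [("miss", 1.0)] * 2 + [("error", 0.4)] * 5
        )
        hit, miss, err = rates(scored)
        assert hit + miss + err == pytest.approx(1.0)
        assert (hit, miss, err) == pytest.approx((0.3, 0.2, 0.5))

    def test_rates_total_ecps_denominator(self):
        scored = _scored(
            [("hit", 0.0)] * 2 + [("miss", 1.0)] + [("error", 0.4)]
        )
        hit, miss, err = rates(scored, n_redundant=2,
                               denominator_mode="total_ecps")
        # denominator = 3 scoring detections + 2 redundant; misses excluded
        assert (hit, miss, err) == pytest.approx((0.4, 0.2, 0.2))

    def test_normalized_times(self):
        assert normalized_times({"A": 1, "B": 1, "C": 2}) == pytest.approx(
            {"A": 0.25, "B": 0.25, "C": 0.5}
        )
        assert normalized_times({"A": 7.0}) == {"A": 1.0}
        with pytest.raises(ValueError):
            normalized_times({"A": 0.0, "B": 0.0})


class TestDistribution:
    def test_counting_and_normalization(self):
        seg = Segment(1, 201, 101)
        scored = [
            ScoredSegment(seg, 81, "error", 0.2, -0.2),
            ScoredSegment(seg, 81, "error", 0.2, -0.2),
            ScoredSegment(seg, 151, "error", 0.5, 0.5),
            ScoredSegment(seg, None, "miss", 1.0, 1.0),
        ]
        bins = frequency_distribution(scored, n_bins=10)
        assert sum(b.freq for b in bins) == pytest.approx(1.0)
        by_value = {
            round(v, 1): next(b for b in bins if b.left <= v < b.right or
                              (v == 1.0 and b.right == 1.0))
            for v in (-0.2, 0.5)
        }
        assert by_value[-0.2].freq == pytest.approx(0.5)
        assert by_value[0.5].freq == pytest.approx(0.25)
        assert bins[-1].count == 1  # the miss sits at +1

    def test_all_hits_concentrate_at_zero(self):
        seg = Segment(1, 201, 101)
        scored = [ScoredSegment(seg, 101, "hit", 0.0, 0.0)] * 100
        bins = frequency_distribution(scored, n_bins=201)
        nonzero = [b for b in bins if b.count]
        assert len(nonzero) == 1
        assert nonzero[0].freq == 1.0
        assert nonzero[0].left < 0 < nonzero[0].right  # centred at 0
        assert nonzero[0].wed_mass == pytest.approx(0.0)

    def test_wed_mass_is_freq_times_center(self):
        bins = wed_distribution(
            [DistributionBin(-0.3, -0.1, 5, 0.5),
             DistributionBin(-0.1, 0.1, 5, 0.5)]
        )
        assert bins[0].wed_mass == pytest.approx(0.5 * 0.2)
        assert bins[1].wed_mass == pytest.approx(0.0)

    def test_fine_binned_mass_matches_mwed(self, rng):
        """Oracle equivalence: sum of freq x |NED| converges to MWED."""
        seg = Segment(1, 201, 101)
        for _ in range(20):
            vals = rng.uniform(-1, 1, int(rng.integers(10, 300)))
            scored = [
                ScoredSegment(seg, 101, "error", abs(v), float(v))
                for v in vals
            ]
            n_bins = 2001
            mass = sum(b.wed_mass for b in frequency_distribution(scored,
                                                                  n_bins))
            assert mass == pytest.approx(mwed(scored), abs=2.0 / n_bins)

    def test_rejects_empty_or_degenerate_bins(self):
        with pytest.raises(ValueError):
            frequency_distribution([], 10)
        seg = Segment(1, 201, 101)
        with pytest.raises(ValueError):
            frequency_distribution(
                [ScoredSegment(seg, 101, "hit", 0.0, 0.0)], 1
            )


def test_mwed_position_only_invariance(rng):
    """MWED depends only on positions, not on the series' values scale."""
    from wedm import TimeSeriesSample, score_run

    values = rng.standard_normal(300)
    cps = [80, 200]
    ecps = np.array([75, 240])
    for transform in (lambda v: v, lambda v: 10 * v + 3):
        sample = TimeSeriesSample(transform(values), cps)
        scored, _ = score_run(sample, ecps, hd=2)
        assert mwed(scored) == pytest.approx(
            mwed(score_run(TimeSeriesSample(values, cps), ecps, hd=2)[0])
        )
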