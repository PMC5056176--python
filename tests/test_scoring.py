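"""Profile scoring, reliability coefficients and segmentation summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from playdyn.core import PROFILES
from playdyn.scoring import (ALL_ITEMS, DEFAULT_PROFILE_ITEMS,
                             MissingItemError, cronbach_alpha, icc_agreement,
                             profile_alphas, score_profiles,
                             segmentation_summary)
from playdyn.simulate import SimulationConfig, generate_cohort

from conftest import make_segment


class TestProfileItemLists:
    def test_item_counts_per_profile(self):
        counts = {p: len(items) for p, items in DEFAULT_PROFILE_ITEMS.items()}
        assert counts == {"adaptive": 12, "inhibited": 9, "impulsive": 10,
                          "disorganized": 9, "engagement": 5}

    def test_shared_items_belong_to_multiple_profiles(self):
        # facilitation of play sits in both Adaptive and Engagement;
        # inhibition of play in the three non-adaptive profiles
        assert "facilitation_of_play" in DEFAULT_PROFILE_ITEMS["adaptive"]
        assert "facilitation_of_play" in DEFAULT_PROFILE_ITEMS["engagement"]
        assert all("inhibition_of_play" in DEFAULT_PROFILE_ITEMS[p]
                   for p in ("inhibited", "impulsive", "disorganized"))

    def test_engagement_items_subset_of_adaptive(self):
        assert set(DEFAULT_PROFILE_ITEMS["engagement"]) <= set(
            DEFAULT_PROFILE_ITEMS["adaptive"])


class TestScoreProfiles:
    def test_constant_input_gives_constant_composites(self):
        scores = score_profiles(make_segment(score=3))
        assert all(getattr(scores, p) == 3.0 for p in PROFILES)

    def test_extreme_adaptive_scores(self):
        seg = make_segment(score=1, **{i: 5 for i in
                                       DEFAULT_PROFILE_ITEMS["adaptive"]})
        scores = score_profiles(seg)
        assert scores.adaptive == 5.0

    def test_engagement_hand_sum(self):
        # engagement items scored (4,5,4,3,4) -> 20/5 = 4.0
        overrides = dict(zip(DEFAULT_PROFILE_ITEMS["engagement"],
                             (4, 5, 4, 3, 4)))
        seg = make_segment(score=3, **overrides)
        assert score_profiles(seg).engagement == pytest.approx(4.0)

    def test_missing_item_names_item_and_profile(self):
        items = {i: 3 for i in ALL_ITEMS if i != "play_alone"}
        seg = make_segment()
        seg = seg.__class__(**{**seg.to_dict(), "item_scores": items})
        with pytest.raises(MissingItemError, match="play_alone.*inhibited"):
            score_profiles(seg)

    @settings(max_examples=50, deadline=None)
    @given(base=st.integers(1, 4),
           item=st.sampled_from(sorted(DEFAULT_PROFILE_ITEMS["disorganized"])))
    def test_monotone_in_every_item(self, base, item):
        low = score_profiles(make_segment(score=base))
        high = score_profiles(make_segment(score=base, **{item: base + 1}))
        for profile in PROFILES:
            assert getattr(high, profile) >= getattr(low, profile)

    def test_item_order_irrelevant(self, rated_segment):
        shuffled = dict(reversed(list(rated_segment.item_scores.items())))
        seg2 = rated_segment.__class__(
            **{**rated_segment.to_dict(), "item_scores": shuffled})
        assert score_profiles(rated_segment) == score_profiles(seg2)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([1, 2, 3, 4, 5.0])
        assert cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_two_uncorrelated_equal_variance_items_give_zero(self):
        # closed form: k=2, zero covariance -> alpha = 0
        a = np.array([1, 1, 2, 2.0])
        b = np.array([1, 2, 1, 2.0])
        assert cronbach_alpha(np.column_stack([a, b])) == pytest.approx(0.0)

    def test_six_by_three_table_matches_formula(self):
        # frozen from a direct evaluation of the standard formula
        X = [[3, 4, 3], [2, 2, 3], [4, 5, 4], [1, 2, 2], [5, 4, 5], [3, 3, 4]]
        assert cronbach_alpha(X) == pytest.approx(0.9178470254957506)

    def test_zero_total_variance_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(cronbach_alpha(np.full((4, 3), 2.0)))

    def test_synthetic_item_scores_reach_reported_range(self):
        # item-level emission with planted state structure: pooled alpha of
        # every profile clears the low end of typical instrument reliability
        cohort = generate_cohort(SimulationConfig(
            n_patients=2, sessions_per_patient=55,
            item_emission="item_level", item_noise_sd=0.3, master_seed=5))
        alphas = profile_alphas(cohort.segments)
        assert all(a >= 0.66 for a in alphas.values()), alphas


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.array([1, 2, 3, 4, 5.0])
        assert icc_agreement(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_pure_noise_rater_drives_icc_down(self, rng):
        signal = rng.normal(3, 0.2, size=200)
        noisy = signal + rng.normal(0, 5.0, size=200)
        assert icc_agreement(np.column_stack([signal, noisy])) < 0.2

    def test_six_by_two_matches_anova_mean_squares(self):
        # frozen from a hand ANOVA: MSR=3.1333, MSC=0.3333, MSE=0.3333
        Y = [[3, 4], [2, 2], [4, 5], [1, 2], [5, 4], [3, 3]]
        assert icc_agreement(Y) == pytest.approx(0.8076923076923076)

    def test_degenerate_table_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(icc_agreement(np.full((5, 2), 3.0)))


class TestSegmentationSummary:
    def test_proportions_sum_to_one(self):
        segs = ([make_segment(session=s, segment=1) for s in range(1, 8)]
                + [make_segment(session=s, segment=2, activity="non_play")
                   for s in range(1, 4)])
        summary = segmentation_summary(segs)
        props = summary.proportions["P01"]
        assert props["non_play"] == pytest.approx(0.3)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_play_segment_selected(self):
        segs = [make_segment(activity="pre_play", segment=1),
                make_segment(segment=2, duration=4.0)]
        assert segmentation_summary(segs).longest_play["P01"][1] == 2

    def test_longest_by_duration(self):
        segs = [make_segment(segment=1, duration=2.0),
                make_segment(segment=2, duration=9.0),
                make_segment(segment=3, duration=5.0)]
        assert segmentation_summary(segs).longest_play["P01"][1] == 2

    def test_tie_breaks_to_earliest(self, caplog):
        segs = [make_segment(segment=1, duration=5.0),
                make_segment(segment=2, duration=5.0)]
        with caplog.at_level("INFO"):
            assert segmentation_summary(segs).longest_play["P01"][1] == 1
        assert any("tie" in r.message for r in caplog.records)

    def test_session_without_play_flagged(self, caplog):
        segs = [make_segment(), make_segment(session=2, activity="non_play")]
        with caplog.at_level("WARNING"):
            summary = segmentation_summary(segs)
        assert ("P01", 2) in summary.sessions_without_play
        assert 2 not in summary.longest_play["P01"]
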