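"""Synthetic-cohort generator: determinism, planted structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from playdyn.core import PROFILES, ClusterCenters
from playdyn.clustering import assign_states
from playdyn.markov import transition_counts, transition_percentages
from playdyn.simulate import (SimulationConfig, default_transition_matrix,
                              generate_cohort, generate_profile_series,
                              stationary_distribution)


class TestConfig:
    def test_default_matrix_is_row_stochastic(self):
        m = default_transition_matrix()
        assert m.shape == (7, 7)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_invalid_stochastic_matrix_rejected(self):
        bad = np.full((7, 7), 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(transition_matrix=bad)

    def test_activity_rates_must_normalise(self):
        rates = {"first": {"pre_play": 0.5, "play": 0.5, "non_play": 0.5,
                           "interruption": 0.5},
                 "second": {"pre_play": 0.25, "play": 0.25, "non_play": 0.25,
                            "interruption": 0.25}}
        with pytest.raises(ValueError, match="sum to"):
            SimulationConfig(activity_rates=rates)

    def test_round_trips_through_dict(self):
        cfg = SimulationConfig(master_seed=7, sessions_per_patient=(40, 60))
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert np.allclose(again.transition_matrix, cfg.transition_matrix)
        assert again.sessions_per_patient == (40, 60)


class TestGenerateCohort:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_patients=2, sessions_per_patient=10,
                               master_seed=3)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.segments == b.segments
        assert a.true_states == b.true_states
        assert a.outcomes == b.outcomes
        pd.testing.assert_frame_equal(a.profiles, b.profiles)

    def test_deterministic_alternation_matrix(self):
        matrix = np.array([[0.0, 1.0], [1.0, 0.0]])
        centers = ClusterCenters(2, np.array([[2.0, 2, 2, 2, 2],
                                              [4.0, 4, 4, 4, 4]]))
        cfg = SimulationConfig(n_patients=3, sessions_per_patient=12,
                               n_states=2, transition_matrix=matrix,
                               state_centers=centers, master_seed=1)
        cohort = generate_cohort(cfg)
        for seq in cohort.true_states:
            diffs = np.abs(np.diff(seq.states))
            assert (diffs == 1).all()  # strict alternation

    def test_noiseless_emission_recovers_states_exactly(self):
        cfg = SimulationConfig(n_patients=2, sessions_per_patient=30,
                               profile_noise_sd=0.0, master_seed=4)
        cohort = generate_cohort(cfg)
        sequences = assign_states(cfg.state_centers, cohort.profiles)
        truth = {s.patient_id: s.states for s in cohort.true_states}
        for seq in sequences:
            assert seq.states == truth[seq.patient_id]

    def test_every_session_has_a_play_segment(self):
        cohort = generate_cohort(SimulationConfig(
            n_patients=1, sessions_per_patient=30, master_seed=8))
        by_session: dict = {}
        for seg in cohort.segments:
            by_session.setdefault(seg.session_index, []).append(
                seg.activity_type)
        assert all("play" in acts for acts in by_session.values())
        sizes = {len(a) for a in by_session.values()}
        assert sizes <= set(range(4, 8))

    def test_item_level_mode_emits_valid_likert_scores(self):
        cfg = SimulationConfig(n_patients=1, sessions_per_patient=10,
                               item_emission="item_level", master_seed=2)
        cohort = generate_cohort(cfg)
        play = [s for s in cohort.segments if s.activity_type == "play"]
        assert play
        for seg in play:
            assert seg.item_scores
            assert all(1 <= v <= 5 for v in seg.item_scores.values())
        # profile scores recomputed from the integer items stay in range
        assert cohort.profiles[list(PROFILES)].to_numpy().min() >= 1
        assert cohort.profiles[list(PROFILES)].to_numpy().max() <= 5

    def test_stationary_frequencies_of_long_chain(self):
        matrix = default_transition_matrix()
        pi = stationary_distribution(matrix)
        cfg = SimulationConfig(n_patients=1, sessions_per_patient=100_000,
                               segments_per_session=(1, 1), master_seed=6)
        # chain only; avoid generating 100k sessions of segments
        from playdyn.simulate import _simulate_chain
        rng = np.random.default_rng(6)
        chain = _simulate_chain(rng, matrix, 100_000)
        freqs = np.bincount(chain - 1, minlength=7) / len(chain)
        assert 0.5 * np.abs(freqs - pi).sum() < 0.01  # total variation

    def test_outcomes_drawn_per_instrument(self):
        cohort = generate_cohort(SimulationConfig(
            n_patients=2, sessions_per_patient=5, master_seed=9))
        assert len(cohort.outcomes) == 6
        instruments = {o.instrument for o in cohort.outcomes}
        assert instruments == {"CBCL-Internalizing", "CBCL-Anxiety", "CGAS"}


class TestEndToEndRecovery:
    def test_transition_recovery_on_large_cohort(self):
        # with enough patients the pooled estimator tightens around truth
        cfg = SimulationConfig(n_patients=60, sessions_per_patient=55,
                               segments_per_session=(1, 1),
                               profile_noise_sd=0.0, master_seed=10)
        cohort = generate_cohort(cfg)
        est = transition_percentages(transition_counts(cohort.true_states))
        err = np.nanmax(np.abs(est.percentages / 100 - cfg.transition_matrix))
        assert err < 0.1


class TestProfileSeries:
    def test_planted_signs_with_default_coupling(self):
        df = generate_profile_series(n_segments=1000, seed=0)
        corr = df.corr()
        assert corr.loc["engagement", "disorganized"] <= -0.3
        assert corr.loc["engagement", "inhibited"] <= -0.3
        assert corr.loc["disorganized", "impulsive"] >= 0.3
        assert corr.loc["disorganized", "inhibited"] >= 0.3
        assert corr.loc["impulsive", "inhibited"] >= 0.3
        assert corr.loc["adaptive", "engagement"] >= 0.3

    def test_zero_coupling_gives_independence(self):
        df = generate_profile_series(n_segments=1000, coupling=0.0, seed=1)
        corr = df.corr().values
        assert np.abs(corr[~np.eye(5, dtype=bool)]).max() < 0.1

    def test_exact_anticorrelation_in_noiseless_limit(self):
        df = generate_profile_series(n_segments=200, adaptive_loading=0.0,
                                     noise_sd=0.0, seed=2)
        r = df["engagement"].corr(df["disorganized"])
        assert r == pytest.approx(-1.0)
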