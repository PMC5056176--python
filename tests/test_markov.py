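"""Transition counting, attractor identification and ergodicity scaling."""

import itertools

import numpy as np
import pytest

from playdyn.core import ClusterCenters, StateSequence
from playdyn.markov import (ergodicity_analysis, find_attractor,
                            state_frequencies, transition_counts,
                            transition_percentages)
from playdyn.simulate import default_transition_matrix, stationary_distribution


class TestTransitionCounts:
    def test_row_four_of_case_study(self, table4_sequences):
        tm = transition_counts(table4_sequences)
        row = {j + 1: int(tm.counts[3, j]) for j in range(7)
               if tm.counts[3, j]}
        assert row == {2: 2, 3: 3, 4: 1}
        assert tm.row_totals[3] == 6

    def test_row_one_of_case_study(self, table4_sequences):
        tm = transition_counts(table4_sequences)
        row = {j + 1: int(tm.counts[0, j]) for j in range(7)
               if tm.counts[0, j]}
        assert row == {1: 1, 3: 1, 5: 1, 6: 2, 7: 1}

    def test_single_self_transition(self):
        tm = transition_counts([StateSequence("P", (2, 2), 7)])
        assert tm.counts[1, 1] == 1
        assert tm.total_transitions == 1

    def test_conservation_and_no_boundary_transitions(self, table4_sequences):
        tm = transition_counts(table4_sequences)
        assert tm.total_transitions == sum(
            len(s) - 1 for s in table4_sequences) == 160
        # pooling is order-invariant across patients
        tm_rev = transition_counts(list(reversed(table4_sequences)))
        assert np.array_equal(tm.counts, tm_rev.counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no sequences"):
            transition_counts([])

    def test_mismatched_state_spaces_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            transition_counts([StateSequence("A", (1, 2), 7),
                               StateSequence("B", (1, 2), 5)])


class TestTransitionPercentages:
    def test_case_study_row_four(self, table4_sequences):
        tm = transition_percentages(transition_counts(table4_sequences))
        assert tm.percentages[3] == pytest.approx(
            [0, 100 / 3, 50, 100 / 6, 0, 0, 0])

    def test_case_study_row_seven_self_loop(self, table4_sequences):
        tm = transition_percentages(transition_counts(table4_sequences))
        assert tm.percentages[6, 6] == pytest.approx(7.69, abs=0.005)

    def test_rows_sum_to_hundred(self, table4_sequences):
        tm = transition_percentages(transition_counts(table4_sequences))
        assert tm.percentages.sum(axis=1) == pytest.approx([100.0] * 7)

    def test_single_transition_row(self):
        tm = transition_percentages(
            transition_counts([StateSequence("P", (1, 3), 3)]))
        assert tm.percentages[0, 2] == 100.0

    def test_never_left_state_flagged_nan(self, caplog):
        tm = transition_counts([StateSequence("P", (1, 1, 2), 3)])
        with caplog.at_level("WARNING"):
            tm = transition_percentages(tm)
        assert np.isnan(tm.percentages[2]).all()
        assert np.isnan(tm.percentages[1]).all()  # state 2 is absorbing-final


class TestEstimatorConsistency:
    def test_long_chain_recovers_planted_matrix(self):
        planted = default_transition_matrix()
        rng = np.random.default_rng(99)
        pi = stationary_distribution(planted)
        n = 100_000
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(7, p=pi)
        for t in range(1, n):
            states[t] = rng.choice(7, p=planted[states[t - 1]])
        seq = StateSequence("sim", tuple(states + 1), 7)
        est = transition_percentages(transition_counts([seq]))
        assert np.nanmax(np.abs(est.percentages / 100 - planted)) < 0.02


class TestAttractor:
    def test_case_study_attractor_is_two_six(self, table4_sequences):
        tm = transition_counts(table4_sequences)
        att = find_attractor(tm)
        assert set(att.pair) == {2, 6}

    def test_perfect_alternation(self):
        seq = StateSequence("P", (1, 2) * 20, 2)
        att = find_attractor(transition_counts([seq]))
        assert att.pair == (1, 2)
        assert att.share == pytest.approx(1.0)

    def test_matches_brute_force_on_random_chain(self, rng):
        states = rng.integers(1, 5, size=10_000)
        seq = StateSequence("P", tuple(states), 4)
        tm = transition_counts([seq])
        att = find_attractor(tm)
        best_pair = max(itertools.combinations(range(4), 2),
                        key=lambda ab: tm.counts[ab[0], ab[1]]
                        + tm.counts[ab[1], ab[0]])
        assert att.pairs[0] == (best_pair[0] + 1, best_pair[1] + 1)

    def test_tie_returns_all_pairs(self):
        seq = StateSequence("P", (1, 2, 1, 3, 1), 3)
        att = find_attractor(transition_counts([seq]))
        assert set(att.pairs) == {(1, 2), (1, 3)}


class TestErgodicity:
    def test_frequency_proportional_chain_scales(self):
        # a chain whose transition probabilities equal the target state's
        # frequency: transition counts must scale with f_i * f_j
        freq = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
        matrix = np.tile(freq, (5, 1))
        rng = np.random.default_rng(3)
        states = rng.choice(5, size=10_000, p=freq) + 1
        seq = StateSequence("sim", tuple(states), 5)
        centers = ClusterCenters(5, np.linspace(1.5, 4.5, 25).reshape(5, 5))
        result = ergodicity_analysis(transition_counts([seq]), centers, [seq])
        assert result.r >= 0.95

    def test_uniform_chain_constant_composite_flagged(self, caplog):
        states = tuple(np.tile([1, 2, 3, 4], 100))
        seq = StateSequence("P", states, 4)
        centers = ClusterCenters(4, np.full((4, 5), 3.0))
        with caplog.at_level("WARNING"):
            result = ergodicity_analysis(transition_counts([seq]), centers,
                                         [seq])
        assert np.isnan(result.r)

    def test_case_study_scaling(self, table4_sequences, table3_centers):
        counts = transition_counts(table4_sequences)
        result = ergodicity_analysis(counts, table3_centers, table4_sequences)
        assert len(result.table) == 42  # off-diagonal ordered pairs
        # strong positive scaling, barely reduced when distance is removed
        assert result.r > 0.8
        assert abs(result.r - result.r_partial) < 0.1
        # brute-force cross-check of the correlation over the same rows
        n = result.table["n_transitions"].to_numpy(dtype=float)
        c = result.table["composite"].to_numpy()
        brute = np.corrcoef(n, c)[0, 1]
        assert result.r == pytest.approx(brute)

    def test_marginal_frequencies_from_pooled_occurrences(
            self, table4_sequences):
        freq = state_frequencies(table4_sequences)
        assert freq.sum() == pytest.approx(1.0)
        # state 2 is the most frequent state in the pooled 163 occurrences
        assert freq.argmax() == 1

    def test_two_state_partial_undefined(self, caplog):
        seq = StateSequence("P", (1, 2, 1, 1, 2, 2, 1), 2)
        centers = ClusterCenters(2, np.array([[2.0, 2, 2, 2, 2],
                                              [4.0, 4, 4, 4, 4]]))
        with caplog.at_level("WARNING"):
            result = ergodicity_analysis(transition_counts([seq]), centers,
                                         [seq])
        assert np.isnan(result.r_partial)
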