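"""Tokens-task machinery: exact probabilities, trial generators, scheduling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satmep import task_model as tm


def enumerate_success_probability(n_left: int, n_right: int, n_center: int) -> float:
    """Brute-force oracle: enumerate all 2**n_center equiprobable
    completions and count those giving the left circle >= 8 tokens."""
    wins = sum(
        1
        for tail in itertools.product("LR", repeat=n_center)
        if n_left + tail.count("L") >= 8
    )
    return wins / 2**n_center


class TestSuccessProbability:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((0, 0, 15), 0.5),  # symmetric start
            ((8, 4, 3), 1.0),  # majority already secured
            ((1, 0, 14), 9908 / 16384),
            ((5, 4, 6), 42 / 64),
            ((0, 8, 7), 0.0),  # lost: empty sum
        ],
    )
    def test_known_states(self, state, expected):
        assert tm.success_probability(*state) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "state", [(-1, 0, 5), (0, -2, 5), (0, 0, -1), (8, 4, 4)]
    )
    def test_invalid_states_rejected(self, state):
        with pytest.raises(ValueError):
            tm.success_probability(*state)

    def test_matches_enumeration_for_all_reachable_states(self):
        # every within-trial state with <= 12 tokens still in the centre
        for n_center in range(13):
            placed = 15 - n_center
            for n_left in range(placed + 1):
                state = (n_left, placed - n_left, n_center)
                assert tm.success_probability(*state) == pytest.approx(
                    enumerate_success_probability(*state), abs=1e-12
                )

    @given(n_center=st.integers(0, 12), data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_complement_and_monotonicity(self, n_center, data):
        # complete mid-trial states: all 15 tokens accounted for, so the
        # odd total rules out ties and the two sides' probabilities sum to 1
        n_left = data.draw(st.integers(0, 15 - n_center))
        n_right = 15 - n_center - n_left
        p_left = tm.success_probability(n_left, n_right, n_center)
        p_right = tm.success_probability(n_right, n_left, n_center)
        assert p_left + p_right == pytest.approx(1.0, abs=1e-12)
        if n_right > 0:  # shift one token to the left circle
            assert tm.success_probability(n_left + 1, n_right - 1, n_center) >= p_left


class TestTrialGeneration:
    @pytest.mark.parametrize("seed", range(8))
    def test_ambiguous_structure_and_bounds(self, seed):
        trial = tm.generate_trial("ambiguous", np.random.default_rng(seed))
        p = tm.success_trajectory(trial)
        # equal counts after even jumps 2..10, lead of one after odd jumps
        for k in range(1, 11):
            n_corr, n_inc, _ = trial.counts_after(k)
            assert n_corr - n_inc == (1 if k % 2 else 0)
        assert np.all(p[1:10:2] == 0.5)
        assert p[8] == pytest.approx(0.65625)
        assert p[14] == 1.0
        assert 0.5 <= p[:10].min() and p[:10].max() <= 0.66

    @pytest.mark.parametrize("seed", range(8))
    def test_obvious_and_misleading_constraints(self, seed):
        rng = np.random.default_rng(seed)
        p_obv = tm.success_trajectory(tm.generate_trial("obvious", rng))
        assert p_obv[2] > 0.7 and p_obv[4] > 0.8
        p_mis = tm.success_trajectory(tm.generate_trial("misleading", rng))
        assert p_mis[2] < 0.4

    def test_random_trial_labels_majority_correct(self, rng):
        for _ in range(20):
            trial = tm.generate_trial("random", rng)
            c = trial.correct_side[0].upper()
            assert trial.jumps.count(c) >= 8

    def test_ambiguous_completion_always_valid(self, rng):
        # the correct side must reach >= 8 tokens for every sampled tail
        for _ in range(50):
            trial = tm.generate_trial("ambiguous", rng)
            assert trial.jumps.count(trial.correct_side[0].upper()) >= 8

    def test_generation_failure_raises(self, rng):
        with pytest.raises(tm.GenerationError):
            tm.generate_trial("obvious", rng, max_attempts=1)


class TestSchedule:
    def test_default_composition_matches_design(self, rng):
        sched = tm.build_session_schedule(rng=rng)
        assert len(sched) == 320
        assert sched.n_stimulated() == 291
        tab = sched.cross_tab()
        assert tab[("ambiguous", "jump1")] == 58
        assert tab[("ambiguous", "jump4")] == 56
        assert tab[("ambiguous", "jump7")] == 56
        assert tab[("ambiguous", "none")] == 17
        assert tab[("random", "baseline")] == 27
        assert sum(n for (t, _), n in tab.items() if t == "obvious") == 49
        assert sum(n for (t, _), n in tab.items() if t == "misleading") == 54

    def test_cross_tab_equals_any_valid_configuration(self, rng):
        comp = {("random", "none"): 320}
        sched = tm.build_session_schedule(comp, rng)
        assert sched.cross_tab() == comp
        assert sched.n_stimulated() == 0

    @pytest.mark.parametrize(
        "comp",
        [
            {("random", "none"): 319},
            {("ambiguous", "baseline"): 320},  # baseline only in random trials
            {("random", "none"): -1, ("random", "baseline"): 321},
        ],
    )
    def test_invalid_composition_rejected(self, comp, rng):
        with pytest.raises(tm.ConfigError):
            tm.build_session_schedule(comp, rng)


class TestPayoffAndTimeline:
    @pytest.mark.parametrize(
        "correct, interval, context, expected",
        [
            (True, 5, "hasty", 10),  # 10 tokens left between Jump_5 and Jump_6
            (True, 5, "cautious", 10),
            (True, 10, "hasty", 5),
            (False, 3, "cautious", -14),
            (False, 3, "hasty", -4),
            (False, None, "hasty", -4),
            (False, None, "cautious", -4),
        ],
    )
    def test_outcome_score(self, correct, interval, context, expected):
        scheme = tm.PayoffScheme.for_context(context)
        assert tm.outcome_score(correct, interval, scheme) == expected

    @pytest.mark.parametrize("interval", [0, 15, -2])
    def test_out_of_range_response_rejected(self, interval):
        with pytest.raises(ValueError):
            tm.outcome_score(True, interval, tm.PayoffScheme.for_context("hasty"))

    def test_reward_non_increasing_in_time(self):
        scheme = tm.PayoffScheme.for_context("cautious")
        rewards = [tm.outcome_score(True, k, scheme) for k in range(1, 15)]
        assert rewards == sorted(rewards, reverse=True)

    def test_timeline_arithmetic(self):
        events = dict((label, t) for t, label in tm.trial_timeline())
        assert events["trial_end"] == 6600
        assert events["jump7"] - events["jump1"] == 1200
        assert events["jump4"] - events["jump1"] == 600
        assert events["jump1"] - events["baseline_pulse"] == 1300
        assert events["jump15"] - events["jump1"] == 2800
        assert events["feedback_onset"] == events["jump15"]

    def test_trial_invariants(self):
        trial = tm.TokenTrial("ambiguous", "left", "LRLRLRLRLRLLLRR")
        assert trial.jump_times_ms[0] == 0
        assert trial.jump_times_ms[6] == 1200
        with pytest.raises(ValueError):
            tm.TokenTrial("ambiguous", "right", "LRLRLRLRLRLLLRR")  # R has < 8
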