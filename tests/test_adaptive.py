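"""Closed-loop controller rules, learner dynamics, and session plumbing."""

import numpy as np
import pytest

from neuroadapt.adaptive import (
    Action, DelayModel, LearnerConfig, LearnerState, QLearningController,
    SessionLog, StateWindow, WINDOW_S, ZPD_BAND, adaptive_policy,
    classify_state, detection_latency, fixed_policy, learner_step,
    preventive_fraction, reward, run_session,
)


class TestClassifyState:
    @pytest.mark.parametrize("tbr,lfhf,eng,t,expected", [
        (2.0, 1.5, 0.7, 10, "overload"),
        (0.0, 0.0, 0.8, 10, "optimal"),
        (-1.0, 0.0, 0.7, 5, "under_challenge"),
        (0.0, 0.0, 0.1, 10, "disengagement"),
        (2.0, 1.5, 0.1, 10, "overload"),  # overload outranks disengagement
    ])
    def test_rules(self, tbr, lfhf, eng, t, expected):
        assert classify_state(tbr, lfhf, eng, t) == expected

    def test_fatigue_needs_decline_time_and_calm_tbr(self):
        kw = dict(tbr_z=0.5, lfhf_z=0.3, engagement=0.6,
                  engagement_trend=-0.05)
        assert classify_state(elapsed_min=30, **kw) == "fatigue"
        assert classify_state(elapsed_min=10, **kw) == "optimal"


class TestPolicies:
    def test_overload_escalation_sequence(self):
        assert adaptive_policy("overload", []).kind == "decrease_difficulty"
        assert adaptive_policy("overload", []).magnitude == 0.20
        assert adaptive_policy("overload",
                               ["overload"]).kind == "switch_modality"
        assert adaptive_policy(
            "overload", ["overload", "overload"]).kind == "recommend_break"

    def test_non_overload_actions(self):
        assert adaptive_policy("optimal", []).kind == "none"
        a = adaptive_policy("under_challenge", [])
        assert (a.kind, a.magnitude) == ("increase_difficulty", 0.10)
        assert adaptive_policy("fatigue", []).kind == "recommend_break"

    def test_fixed_schedule_fires_only_on_marks(self):
        assert fixed_policy(10.0).kind == "increase_difficulty"
        assert fixed_policy(25.0).kind == "none"
        assert fixed_policy(40.0).kind == "increase_difficulty"
        with pytest.raises(ValueError):
            fixed_policy(-1.0)

    def test_fixed_difficulty_after_25_min_is_1_21x(self, flat_profiles):
        ls = LearnerState()
        rng = np.random.default_rng(0)
        for i in range(50):  # 25 min of windows
            a = fixed_policy(i * WINDOW_S / 60.0)
            ls, _ = learner_step(ls, a, rng)
        assert ls.difficulty == pytest.approx(1.21)


class TestReward:
    @pytest.mark.parametrize("args,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 0.0, 1.0), 0.7),
        ((0.2, 0.5, 0.5), 0.05),
    ])
    def test_weighted_sum(self, args, expected):
        assert reward(*args) == pytest.approx(expected)

    def test_unnormalized_weights_warn_and_renormalize(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            r = reward(1.0, 0.0, 0.0, weights=(1.0, 0.6, 0.4))
        assert r == pytest.approx(0.5)


class TestLearnerStep:
    def test_easy_material_drives_load_down(self):
        ls = LearnerState(skill=3.0, difficulty=0.5)
        cfg = LearnerConfig(load_noise_sd=0.0, load_noise_sd_adhd=0.0)
        ls, em = learner_step(ls, Action("none"), np.random.default_rng(0),
                              cfg=cfg)
        assert em["latent_load"] < 0.1

    def test_hard_material_drives_load_up(self):
        ls = LearnerState(skill=0.5, difficulty=3.0)
        cfg = LearnerConfig(load_noise_sd=0.0, load_noise_sd_adhd=0.0)
        ls, em = learner_step(ls, Action("none"), np.random.default_rng(0),
                              cfg=cfg)
        assert em["latent_load"] > 0.9

    def test_break_strictly_reduces_fatigue(self):
        ls = LearnerState(fatigue=0.5)
        ls2, _ = learner_step(ls, Action("recommend_break"),
                              np.random.default_rng(0))
        assert ls2.fatigue < 0.5

    def test_difficulty_respects_floor_and_ceiling(self):
        rng = np.random.default_rng(0)
        ls = LearnerState()
        for _ in range(40):
            ls, _ = learner_step(ls, Action("decrease_difficulty", 0.20),
                                 rng)
        assert ls.difficulty == pytest.approx(0.1 * ls.base_difficulty)
        for _ in range(40):
            ls, _ = learner_step(ls, Action("increase_difficulty", 0.10),
                                 rng)
        assert ls.difficulty == pytest.approx(3.0 * ls.base_difficulty)


class TestRunSession:
    def test_45_minutes_gives_90_windows(self, flat_profiles):
        log = run_session(flat_profiles["ASD"], "adaptive", seed=1)
        assert len(log.windows) == 90
        assert log.duration_s == pytest.approx(2700.0)

    def test_same_seed_identical_logs(self, flat_profiles):
        a = run_session(flat_profiles["TD"], "adaptive", seed=4)
        b = run_session(flat_profiles["TD"], "adaptive", seed=4)
        assert [w.state for w in a.windows] == [w.state for w in b.windows]
        assert a.items_mastered == b.items_mastered

    def test_fixed_policy_fires_exactly_four_increases(self, flat_profiles):
        log = run_session(flat_profiles["SLD"], "fixed", seed=2)
        incr = [a for a in log.actions if a.kind == "increase_difficulty"]
        assert len(incr) == 4
        assert [a.t / 60.0 for a in incr] == [10.0, 20.0, 30.0, 40.0]

    def test_state_occupancy_sums_to_100(self, flat_profiles):
        log = run_session(flat_profiles["ADHD"], "reactive", seed=3)
        assert sum(log.state_occupancy.values()) == pytest.approx(100.0)

    def test_unknown_policy_rejected(self, flat_profiles):
        with pytest.raises(ValueError, match="unknown policy"):
            run_session(flat_profiles["TD"], "oracle", seed=0)

    def test_reactive_with_zero_delay_acts_like_adaptive_on_overload(
            self, flat_profiles):
        fast = DelayModel(lag_mean=0, lag_sd=0, reaction_mean=0,
                          reaction_sd=0, reaction_floor=0)
        log = run_session(flat_profiles["ADHD"], "reactive", seed=5,
                          delay_model=fast)
        lat, n_on, _ = detection_latency(log)
        if n_on:
            assert lat <= 2 * WINDOW_S

    def test_closed_loop_stability_without_noise(self, flat_profiles):
        cfg = LearnerConfig(load_noise_sd=0.0, load_noise_sd_adhd=0.0,
                            emission_noise=0.0, engagement_noise=0.0)
        log = run_session(flat_profiles["TD"], "adaptive", seed=6, cfg=cfg)
        loads = [w.latent_load for w in log.windows[5:]]
        in_band = np.mean([ZPD_BAND[0] <= ld <= ZPD_BAND[1] for ld in loads])
        assert in_band >= 0.8


def make_log(onsets, manifests, ends, action_times):
    return SessionLog(
        windows=[StateWindow(0, 0.0, 0, 0, 1.0, "optimal", 0.5)],
        actions=[Action("decrease_difficulty", 0.2, t)
                 for t in action_times],
        items_mastered=0, items_attempted=0, condition="adaptive",
        duration_s=2700.0, overload_onsets=onsets, manifest_times=manifests,
        episode_ends=ends)


class TestLatencyBookkeeping:
    def test_same_window_action_bounded_by_grid(self):
        log = make_log([100.0], [141.0], [200.0], [120.0])
        lat, n, cens = detection_latency(log)
        assert lat <= WINDOW_S and n == 1 and cens == 0

    def test_no_action_is_censored(self):
        log = make_log([100.0], [141.0], [200.0], [])
        lat, n, cens = detection_latency(log)
        assert np.isnan(lat) and cens == n == 1

    def test_preventive_iff_before_manifestation(self):
        early = make_log([100.0], [141.0], [200.0], [120.0])
        late = make_log([100.0], [141.0], [200.0], [180.0])
        assert preventive_fraction(early) == 100.0
        assert preventive_fraction(late) == 0.0


class TestQLearning:
    def test_decide_returns_repertoire_action(self):
        q = QLearningController(seed=0)
        a = q.decide("overload")
        assert a.kind in ("none", "decrease_difficulty",
                          "increase_difficulty", "switch_modality",
                          "recommend_break")

    def test_update_moves_q_toward_reward(self):
        q = QLearningController(alpha=0.5, gamma=0.0, epsilon=0.0, seed=0)
        before = q.q["overload"]["decrease_difficulty"]
        q.update("overload", Action("decrease_difficulty", 0.2), 1.0,
                 "optimal")
        assert q.q["overload"]["decrease_difficulty"] > before

    def test_runs_inside_session_loop(self, flat_profiles):
        q = QLearningController(seed=1)
        log = run_session(flat_profiles["ADHD"], "adaptive", seed=7,
                          controller=q)
        assert len(log.windows) == 90
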