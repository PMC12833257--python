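"""Closed-loop adaptive difficulty control and its evaluation.

Every 30 s the controller reads three physiological indicators — the frontal
theta/beta ratio z-scored against the participant's resting baseline (TBR z),
an LF/HF z-score, and a gaze-engagement score — classifies the learner's
state, and acts:

* ``overload`` (TBR z > 1.5 and LF/HF z > 1.0): reduce difficulty by 20%;
  on the second consecutive overload switch presentation modality; on the
  third recommend a break.
* ``under_challenge`` (TBR z < −0.5 with engagement ≥ 0.6): raise difficulty
  by 10%.
* ``disengagement`` (engagement < 0.3): switch modality.
* ``fatigue`` (declining engagement trend after 25 min, TBR not elevated):
  recommend a break.
* ``optimal``: no action.

States are evaluated in the priority order overload > disengagement >
fatigue > under_challenge > optimal. Difficulty is clamped to [0.1, 3] ×
base and never increased during overload or fatigue.

Three policies are compared: **adaptive** (the controller above), **fixed**
(pre-programmed +10% difficulty at minutes 10/20/30/40), and **reactive**
(a therapist acting on observable behavior only: the same action repertoire,
but triggered only after the latent state has manifested behaviorally —
a lag of ~N(41.2, 17.8) s — plus a therapist reaction time ~N(20, 5) s).

The learner is a latent-state simulator: cognitive load is a logistic
function of the difficulty−skill gap plus a fatigue term; mastery
probability peaks when load sits in the zone-of-proximal-development (ZPD)
band [0.4, 0.7]; skill grows with mastered items; fatigue accrues with time
and load and decays during breaks. A scalar reward
``r = α·Δperformance − β·load_penalty + γ·engagement`` (α, β, γ = 0.5, 0.3,
0.2) is logged per window for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from neuroadapt.synth.profiles import ParticipantProfile

STATES = ("optimal", "under_challenge", "overload", "fatigue", "disengagement")
POLICIES = ("adaptive", "reactive", "fixed")
WINDOW_S = 30.0
ZPD_BAND = (0.4, 0.7)
REWARD_WEIGHTS = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class StateThresholds:
    overload_tbr_z: float = 1.5
    overload_lfhf_z: float = 1.0
    under_challenge_tbr_z: float = -0.5
    under_challenge_engagement: float = 0.6
    disengagement_engagement: float = 0.3
    fatigue_elapsed_min: float = 25.0
    fatigue_trend: float = -0.02  # engagement slope per window
    fatigue_engagement_max: float = 0.75  # no fatigue call while fully engaged


@dataclass(frozen=True)
class BaselineStats:
    """Per-participant resting statistics the controller z-scores against."""
    tbr_mean: float
    tbr_sd: float
    lfhf_mean: float = 0.0
    lfhf_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.tbr_sd <= 0 or self.lfhf_sd <= 0:
            raise ValueError("baseline SDs must be positive")

    def tbr_z(self, tbr: float) -> float:
        return (tbr - self.tbr_mean) / self.tbr_sd

    def lfhf_z(self, lfhf: float) -> float:
        return (lfhf - self.lfhf_mean) / self.lfhf_sd


@dataclass(frozen=True)
class Action:
    kind: str  # none | decrease_difficulty | increase_difficulty | switch_modality | recommend_break
    magnitude: float = 0.0
    t: float = 0.0


@dataclass
class LearnerConfig:
    """Latent learner dynamics (invented plumbing; see docs)."""
    load_width: float = 0.3          # logistic width of the difficulty-skill gap
    fatigue_load_gain: float = 0.5   # how much fatigue raises latent load
    mastery_peak_p: float = 0.075    # per-window mastery probability inside ZPD
    # mastery falloff outside the ZPD band is asymmetric: under-challenge
    # degrades learning gently (easy items are still learnable), overload
    # sharply (dysregulated learners master almost nothing)
    zpd_falloff_low: float = 0.15
    zpd_falloff_high: float = 0.06
    mastery_eng_floor: float = 0.3   # mastery scales with (floor + (1-floor)*engagement)
    skill_gain: float = 0.04         # skill increment per mastered item
    fatigue_rate: tuple[float, float] = (0.00012, 0.00035)  # per s: base, ×load
    break_recovery: float = 0.25
    load_noise_sd: float = 0.09      # stationary SD of latent load fluctuation
    load_noise_sd_adhd: float = 0.16  # ADHD: larger attention fluctuations
    load_noise_rho: float = 0.6      # AR(1) persistence of attention lapses
    dysreg_gain: float = 0.35        # dysregulation build-up per overloaded window
    dysreg_decay: float = 0.95       # per-window spontaneous decay (slow)
    dysreg_relief: float = 0.25      # remaining fraction after a corrective action
    dysreg_load: float = 0.20        # extra load per unit dysregulation
    dysreg_mastery: float = 0.8      # mastery suppression per unit dysregulation
    dysreg_engagement: float = 0.4   # engagement suppression per unit dysregulation
    tbr_gain: float = 6.0            # TBR z per unit (load − 0.45): z=1.5 at load 0.70
    lfhf_gain: float = 4.8
    emission_noise: float = 0.25
    engagement_noise: float = 0.04


@dataclass
class LearnerState:
    skill: float = 1.0
    difficulty: float = 1.0
    base_difficulty: float = 1.0
    fatigue: float = 0.0
    engagement: float = 1.0
    modality: str = "visual"
    attempted: int = 0
    mastered: int = 0
    load: float = 0.5  # latent cognitive load [0, 1]
    load_noise: float = 0.0  # AR(1) attention-fluctuation state
    dysregulation: float = 0.0  # lingering stress after uncorrected overload


@dataclass
class StateWindow:
    index: int
    start_s: float
    tbr_z: float
    lfhf_z: float
    engagement: float
    state: str
    latent_load: float
    reward: float = 0.0


@dataclass
class SessionLog:
    windows: list[StateWindow]
    actions: list[Action]
    items_mastered: int
    items_attempted: int
    condition: str
    duration_s: float
    overload_onsets: list[float] = field(default_factory=list)
    manifest_times: list[float] = field(default_factory=list)
    episode_ends: list[float] = field(default_factory=list)

    @property
    def state_occupancy(self) -> dict[str, float]:
        n = len(self.windows)
        return {s: 100.0 * sum(w.state == s for w in self.windows) / n
                for s in STATES}


# ------------------------------------------------------------------ policy

def classify_state(tbr_z: float, lfhf_z: float, engagement: float,
                   elapsed_min: float,
                   thresholds: StateThresholds = StateThresholds(),
                   engagement_trend: float = 0.0) -> str:
    """Deterministic rule-based state classification (priority-ordered)."""
    th = thresholds
    if tbr_z > th.overload_tbr_z and lfhf_z > th.overload_lfhf_z:
        return "overload"
    if engagement < th.disengagement_engagement:
        return "disengagement"
    if (engagement_trend < th.fatigue_trend
            and engagement < th.fatigue_engagement_max
            and elapsed_min >= th.fatigue_elapsed_min
            and tbr_z <= th.overload_tbr_z):
        return "fatigue"
    if (tbr_z < th.under_challenge_tbr_z
            and engagement >= th.under_challenge_engagement):
        return "under_challenge"
    return "optimal"


def adaptive_policy(state: str, history: list[str], t: float = 0.0) -> Action:
    """Escalating response: reduce 20% → switch modality → recommend break
    for consecutive overloads; +10% on under-challenge."""
    if state == "overload":
        streak = 1
        for prev in reversed(history):
            if prev == "overload":
                streak += 1
            else:
                break
        if streak == 1:
            return Action("decrease_difficulty", 0.20, t)
        if streak == 2:
            return Action("switch_modality", 0.0, t)
        return Action("recommend_break", 0.0, t)
    if state == "under_challenge":
        return Action("increase_difficulty", 0.10, t)
    if state == "fatigue":
        return Action("recommend_break", 0.0, t)
    if state == "disengagement":
        return Action("switch_modality", 0.0, t)
    return Action("none", 0.0, t)


def fixed_policy(elapsed_min: float, window_min: float = WINDOW_S / 60.0) -> Action:
    """+10% difficulty exactly at minutes 10, 20, 30, 40."""
    if elapsed_min < 0:
        raise ValueError("elapsed time must be non-negative")
    for mark in (10.0, 20.0, 30.0, 40.0):
        if mark <= elapsed_min < mark + window_min:
            return Action("increase_difficulty", 0.10, elapsed_min * 60.0)
    return Action("none", 0.0, elapsed_min * 60.0)


@dataclass(frozen=True)
class DelayModel:
    """Reactive condition timing: behavioral-manifestation lag of latent
    states plus therapist reaction time (both truncated normals, seconds)."""
    lag_mean: float = 41.2
    lag_sd: float = 17.8
    reaction_mean: float = 20.0
    reaction_sd: float = 5.0
    reaction_floor: float = 5.0

    def draw_lag(self, rng: np.random.Generator) -> float:
        return max(rng.normal(self.lag_mean, self.lag_sd), 0.0)

    def draw_reaction(self, rng: np.random.Generator) -> float:
        return max(rng.normal(self.reaction_mean, self.reaction_sd),
                   self.reaction_floor)


def reward(delta_performance: float, load_penalty: float,
           engagement_level: float,
           weights: tuple[float, float, float] = REWARD_WEIGHTS) -> float:
    """r = α·Δperformance − β·load_penalty + γ·engagement."""
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        warnings.warn("reward weights do not sum to 1; renormalizing",
                      stacklevel=2)
        w = w / w.sum()
    a, b, g = w
    return float(a * delta_performance - b * load_penalty
                 + g * engagement_level)


# ----------------------------------------------------------------- learner

def _zpd_factor(load: float, cfg: LearnerConfig) -> float:
    lo, hi = ZPD_BAND
    if lo <= load <= hi:
        return 1.0
    if load < lo:
        return float(np.exp(-0.5 * ((load - lo) / cfg.zpd_falloff_low) ** 2))
    return float(np.exp(-0.5 * ((load - hi) / cfg.zpd_falloff_high) ** 2))


def learner_step(
    ls: LearnerState,
    action: Action,
    rng: np.random.Generator,
    dt: float = WINDOW_S,
    cfg: LearnerConfig = LearnerConfig(),
    group: str = "TD",
) -> tuple[LearnerState, dict[str, float]]:
    """Advance the latent learner one window and emit observables."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    ls = replace(ls)
    on_break = action.kind == "recommend_break"
    if action.kind in ("decrease_difficulty", "switch_modality",
                       "recommend_break"):
        # co-regulation: any corrective action largely clears lingering
        # dysregulation (the point of early intervention)
        ls.dysregulation *= cfg.dysreg_relief
    if action.kind == "decrease_difficulty":
        ls.difficulty *= (1.0 - action.magnitude)
    elif action.kind == "increase_difficulty":
        ls.difficulty *= (1.0 + action.magnitude)
    elif action.kind == "switch_modality":
        ls.modality = "auditory" if ls.modality == "visual" else "visual"
        ls.engagement = min(ls.engagement + 0.15, 1.0)  # novelty boost
    elif on_break:
        ls.fatigue = max(ls.fatigue - cfg.break_recovery, 0.0)
    ls.difficulty = float(np.clip(ls.difficulty, 0.1 * ls.base_difficulty,
                                  3.0 * ls.base_difficulty))

    gap = (ls.difficulty - ls.skill) / cfg.load_width
    noise_sd = (cfg.load_noise_sd_adhd if group == "ADHD"
                else cfg.load_noise_sd)
    rho = cfg.load_noise_rho
    ls.load_noise = (rho * ls.load_noise
                     + np.sqrt(1.0 - rho**2) * rng.normal(0.0, noise_sd))
    load_core = (1.0 / (1.0 + np.exp(-gap))
                 + cfg.fatigue_load_gain * ls.fatigue + ls.load_noise)
    # overload is self-perpetuating: dysregulation builds while the core
    # load sits above the ZPD ceiling and decays only slowly on its own
    ls.dysregulation = float(np.clip(
        ls.dysregulation * cfg.dysreg_decay
        + cfg.dysreg_gain * (load_core > ZPD_BAND[1]), 0.0, 1.0))
    load = float(np.clip(load_core + cfg.dysreg_load * ls.dysregulation,
                         0.0, 1.0))
    ls.load = load

    mastered = 0
    if not on_break:
        ls.attempted += 1
        eng_factor = (cfg.mastery_eng_floor
                      + (1.0 - cfg.mastery_eng_floor) * ls.engagement)
        dysreg_factor = max(1.0 - cfg.dysreg_mastery * ls.dysregulation, 0.0)
        if rng.random() < (cfg.mastery_peak_p * _zpd_factor(load, cfg)
                           * eng_factor * dysreg_factor):
            mastered = 1
            ls.mastered += 1
            ls.skill += cfg.skill_gain
    base, per_load = cfg.fatigue_rate
    ls.fatigue = float(np.clip(
        ls.fatigue + (base + per_load * load) * dt * (0.0 if on_break else 1.0),
        0.0, 1.0))

    # engagement: inverted-U in load (boredom hurts less than overload),
    # minus fatigue
    eng = (1.0
           - 1.2 * max(0.55 - load, 0.0)
           - 2.2 * max(load - 0.55, 0.0)
           - 0.6 * ls.fatigue
           - cfg.dysreg_engagement * ls.dysregulation)
    eng = float(np.clip(eng + rng.normal(0.0, cfg.engagement_noise), 0.0, 1.0))
    ls.engagement = eng

    emissions = {
        "tbr_z": cfg.tbr_gain * (load - 0.45)
        + rng.normal(0.0, cfg.emission_noise),
        "lfhf_z": cfg.lfhf_gain * (load - 0.45)
        + rng.normal(0.0, cfg.emission_noise),
        "engagement": eng,
        "mastered": float(mastered),
        "latent_load": load,
    }
    return ls, emissions


# ------------------------------------------------------------ session loop

def run_session(
    profile: ParticipantProfile,
    policy: str,
    duration_min: float = 45.0,
    seed: int = 0,
    cfg: LearnerConfig = LearnerConfig(),
    thresholds: StateThresholds = StateThresholds(),
    delay_model: DelayModel = DelayModel(),
    controller: "QLearningController | None" = None,
) -> SessionLog:
    """Simulate one closed-loop session under the given policy.

    ``controller`` swaps the adaptive rule policy for a learning controller
    (e.g. :class:`QLearningController`); it is consulted for the action and
    updated with each window's logged reward."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected {POLICIES}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [profile.seed, seed, 606, POLICIES.index(policy)]))
    n_windows = int(round(duration_min * 60.0 / WINDOW_S))
    ls = LearnerState()
    baseline = BaselineStats(tbr_mean=profile.resting_tbr[0],
                             tbr_sd=profile.resting_tbr[1])

    windows: list[StateWindow] = []
    actions: list[Action] = []
    state_history: list[str] = []
    eng_history: list[float] = []
    onsets: list[float] = []
    manifests: list[float] = []
    ep_ends: list[float] = []
    pending: list[tuple[float, str]] = []  # reactive: (actionable time, kind)
    last_load = ls.load
    in_overload = False
    in_boredom = False
    action = Action("none", 0.0, 0.0)
    prev_perf = 0.0

    for i in range(n_windows):
        t = i * WINDOW_S
        elapsed_min = t / 60.0
        # decide this window's action from the previous window's observables
        if i == 0:
            action = Action("none", 0.0, t)
        elif policy == "adaptive":
            if controller is not None:
                action = controller.decide(state_history[-1], t=t)
            else:
                action = replace(adaptive_policy(state_history[-1],
                                                 state_history[:-1]), t=t)
        elif policy == "fixed":
            action = fixed_policy(elapsed_min)
        else:  # reactive: act only on manifested, still-current problems
            action = Action("none", 0.0, t)
            due = [p for p in pending if p[0] <= t]
            if due:
                kind = due[0][1]
                still = ((kind == "overload" and last_load > ZPD_BAND[1])
                         or (kind == "boredom" and last_load < ZPD_BAND[0]))
                if still:
                    if kind == "overload":
                        streak = sum(1 for a in actions[-3:]
                                     if a.kind != "none")
                        action = (Action("decrease_difficulty", 0.20, t)
                                  if streak == 0 else
                                  Action("switch_modality", 0.0, t)
                                  if streak == 1 else
                                  Action("recommend_break", 0.0, t))
                    else:
                        action = Action("increase_difficulty", 0.10, t)
                pending = [p for p in pending if p[0] > t]

        ls, em = learner_step(ls, action, rng, dt=WINDOW_S, cfg=cfg,
                              group=profile.group)
        # raw TBR emitted against the participant's own resting baseline,
        # re-z-scored by the controller (individualized thresholds)
        raw_tbr = baseline.tbr_mean + em["tbr_z"] * baseline.tbr_sd
        tbr_z = baseline.tbr_z(raw_tbr)
        trend = 0.0
        if len(eng_history) >= 3:
            recent = np.array(eng_history[-4:] + [em["engagement"]])
            trend = float(np.polyfit(np.arange(recent.size), recent, 1)[0])
        state = classify_state(tbr_z, em["lfhf_z"], em["engagement"],
                               elapsed_min, thresholds, trend)

        # latent overload bookkeeping: an episode opens at an upward
        # crossing of the ZPD ceiling (onset timed at the window midpoint,
        # where the crossing is expected) and closes when load returns below
        # the ceiling
        if em["latent_load"] > ZPD_BAND[1] and not in_overload:
            in_overload = True
            onset_t = t + WINDOW_S / 2.0
            onsets.append(onset_t)
            lag = delay_model.draw_lag(rng)
            manifests.append(onset_t + lag)
            if policy == "reactive":
                pending.append(
                    (onset_t + lag + delay_model.draw_reaction(rng),
                     "overload"))
        elif em["latent_load"] <= ZPD_BAND[1] and in_overload:
            in_overload = False
            ep_ends.append(t + WINDOW_S / 2.0)
        if policy == "reactive":
            if em["latent_load"] < ZPD_BAND[0] and not in_boredom:
                in_boredom = True
                lag = delay_model.draw_lag(rng)
                pending.append(
                    (t + WINDOW_S / 2.0 + lag
                     + delay_model.draw_reaction(rng), "boredom"))
            elif em["latent_load"] >= ZPD_BAND[0]:
                in_boredom = False
        last_load = em["latent_load"]

        perf = em["mastered"]
        r = reward(perf - prev_perf, max(em["latent_load"] - ZPD_BAND[1], 0.0),
                   em["engagement"])
        prev_perf = perf
        if (controller is not None and policy == "adaptive"
                and state_history):
            controller.update(state_history[-1], action, r, state)
        windows.append(StateWindow(
            index=i, start_s=t, tbr_z=tbr_z, lfhf_z=em["lfhf_z"],
            engagement=em["engagement"], state=state,
            latent_load=em["latent_load"], reward=r))
        actions.append(action)
        state_history.append(state)
        eng_history.append(em["engagement"])

    if in_overload:
        ep_ends.append(n_windows * WINDOW_S)
    return SessionLog(windows=windows, actions=actions,
                      items_mastered=ls.mastered, items_attempted=ls.attempted,
                      condition=policy, duration_s=n_windows * WINDOW_S,
                      overload_onsets=onsets, manifest_times=manifests,
                      episode_ends=ep_ends)


# ---------------------------------------------------------------- analysis

_CORRECTIVE = ("decrease_difficulty", "switch_modality", "recommend_break")


def detection_latency(log: SessionLog,
                      grace_s: float = 90.0) -> tuple[float, int, int]:
    """Mean seconds from latent overload onset to the first corrective
    action answering that episode; actions count only up to ``grace_s``
    after the episode ends. Returns (mean latency, n onsets, n censored)."""
    if not log.overload_onsets:
        return float("nan"), 0, 0
    corrective = sorted(a.t for a in log.actions if a.kind in _CORRECTIVE)
    latencies = []
    censored = 0
    for onset, end in zip(log.overload_onsets, log.episode_ends):
        after = [t for t in corrective if onset <= t <= end + grace_s]
        if after:
            latencies.append(after[0] - onset)
        else:
            censored += 1
    mean = float(np.mean(latencies)) if latencies else float("nan")
    return mean, len(log.overload_onsets), censored


def preventive_fraction(log: SessionLog) -> float:
    """Percent of corrective actions issued before the behavioral
    manifestation of the overload episode they answer."""
    episodes = list(zip(log.overload_onsets, log.manifest_times,
                        log.episode_ends))
    if not episodes:
        return float("nan")
    corrective = [a.t for a in log.actions if a.kind in _CORRECTIVE]
    answered = []
    for onset, manifest, end in episodes:
        after = [t for t in corrective if onset <= t <= end + 90.0]
        if after:
            answered.append((after[0], manifest))
    if not answered:
        return 0.0
    return 100.0 * np.mean([t < m for t, m in answered])


def summarize_session(log: SessionLog) -> dict[str, float]:
    hours = log.duration_s / 3600.0
    occ = log.state_occupancy
    tbr = [w.tbr_z for w in log.windows]
    tail = tbr[-10:]
    latency, n_on, n_cens = detection_latency(log)
    return {
        "items_per_hour": log.items_mastered / hours,
        "completion_frac": (log.items_mastered / log.items_attempted
                            if log.items_attempted else float("nan")),
        "mean_tbr_z": float(np.mean(tbr)),
        "peak_tbr_z": float(np.mean(tail)),
        **{f"pct_{s}": occ[s] for s in STATES},
        "detection_latency_s": latency,
        "n_overload_onsets": float(n_on),
        "n_censored": float(n_cens),
        "preventive_pct": preventive_fraction(log),
        "mean_reward": float(np.mean([w.reward for w in log.windows])),
    }


def compare_conditions(
    profiles: list[ParticipantProfile],
    n_sessions: int = 2,
    seed: int = 0,
    duration_min: float = 45.0,
    cfg: LearnerConfig = LearnerConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every profile through all three policies (Latin-square condition
    ordering, ``n_sessions`` per condition) and summarize per condition.

    Returns (per-session rows, per-condition mean/SD summary).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    square = [list(np.roll(POLICIES, -k)) for k in range(3)]
    for p_idx, profile in enumerate(profiles):
        order = square[p_idx % 3]
        for s_idx in range(n_sessions):
            for c_idx, policy in enumerate(order):
                log = run_session(profile, policy, duration_min=duration_min,
                                  seed=seed + 17 * s_idx + c_idx, cfg=cfg)
                row = {"participant": profile.pid, "group": profile.group,
                       "condition": policy, "session": s_idx,
                       "order_position": c_idx}
                row.update(summarize_session(log))
                rows.append(row)
    per_session = pd.DataFrame(rows)
    value_cols = [c for c in per_session.columns
                  if c not in ("participant", "group", "condition", "session",
                               "order_position")]
    summary = (per_session.groupby("condition")[value_cols]
               .agg(["mean", "std"]))
    return per_session, summary


# ------------------------------------------------- optional RL controller

ACTION_KINDS = ("none", "decrease_difficulty", "increase_difficulty",
                "switch_modality", "recommend_break")


class QLearningController:
    """Optional tabular Q-learning alternative to the rule policy.

    States are the five controller states, actions the five action kinds;
    updates use the logged per-window reward with an ε-greedy behaviour
    policy. The table is initialized from the rule policy's preferred
    actions so exploration starts from sensible behaviour.
    """

    def __init__(self, alpha: float = 0.2, gamma: float = 0.9,
                 epsilon: float = 0.1, seed: int = 0) -> None:
        self.alpha, self.gamma, self.epsilon = alpha, gamma, epsilon
        self.rng = np.random.default_rng(seed)
        self.q = {s: {a: 0.0 for a in ACTION_KINDS} for s in STATES}
        for s in STATES:
            preferred = adaptive_policy(s, []).kind
            self.q[s][preferred] = 0.1

    def decide(self, state: str, t: float = 0.0) -> Action:
        if self.rng.random() < self.epsilon:
            kind = str(self.rng.choice(ACTION_KINDS))
        else:
            kind = max(self.q[state], key=self.q[state].get)
        mag = {"decrease_difficulty": 0.20,
               "increase_difficulty": 0.10}.get(kind, 0.0)
        return Action(kind, mag, t)

    def update(self, state: str, action: Action, r: float,
               next_state: str) -> None:
        best_next = max(self.q[next_state].values())
        q = self.q[state][action.kind]
        self.q[state][action.kind] = q + self.alpha * (
            r + self.gamma * best_next - q)
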