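"""Synthetic gaze: an alternating fixation/saccade renewal process rendered
at 1200 Hz.

Fixation durations are lognormal with the profile's mean/SD; saccades follow
a main-sequence duration rule (21 ms + 2.2 ms/deg) with a raised-cosine
position profile. Within fixations the eye drifts as a low-amplitude AR(1)
tremor, and microsaccades (small raised-cosine excursions, 0.3–0.5°, ~25 ms)
occur as a Poisson process at the profile rate. Blinks are validity-loss
runs inserted between fixations — masking the intervening saccade, as real
blinks do — so measured fixation durations are not split. Pupil diameter is
a noisy low-pass baseline scaled to the target variance.

Task geometries:

* ``freeview`` / ``social`` — jump targets drawn at the profile's saccade
  amplitude; the landing point is steered into / out of on-task AOIs with
  probability equal to the on-task-gaze target.
* ``reading`` — fixations advance left-to-right along text lines with
  leftward regressions at the profile rate; line-return sweeps change lines
  (|Δy| > 1°) and are excluded from the regression statistic by convention.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from neuroadapt.signals import AOI, GazeStream
from neuroadapt.synth.profiles import ParticipantProfile

SCREEN_X, SCREEN_Y = 16.0, 12.0  # half-extent in degrees
TASKS = ("freeview", "reading", "social")

_DRIFT_RHO = 0.995
_DRIFT_STEP = 0.003       # deg per sample
_MS_DUR_S = 0.025         # microsaccade duration
_TREMOR_SEED_OFF = 404


def default_aoi_layout(task: str) -> list[AOI]:
    if task == "reading":
        return [AOI("text", -12.0, -7.5, 12.0, 7.5, ("on_task",)),
                AOI("margin", -16.0, -12.0, 16.0, -7.5, ("off_task",))]
    if task == "social":
        return [AOI("face", -10.0, -2.0, 0.0, 8.0, ("on_task", "social")),
                AOI("toy", 0.0, -8.0, 10.0, 2.0, ("on_task", "non_social")),
                AOI("background", -16.0, -12.0, -10.0, 12.0, ("off_task",))]
    return [AOI("task_panel", -10.0, -8.0, 10.0, 8.0, ("on_task",)),
            AOI("periphery_left", -16.0, -12.0, -10.0, 12.0, ("off_task",)),
            AOI("periphery_right", 10.0, -12.0, 16.0, 12.0, ("off_task",))]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _on_task(aois: list[AOI], x: float, y: float) -> bool:
    return any(a.contains(x, y) for a in aois if "on_task" in a.tags)


def _sample_with_membership(rng, aois, want_on: bool) -> np.ndarray:
    """Uniform screen point with the requested on-task membership."""
    for _ in range(200):
        p = np.array([rng.uniform(-SCREEN_X + 0.5, SCREEN_X - 0.5),
                      rng.uniform(-SCREEN_Y + 0.5, SCREEN_Y - 0.5)])
        if _on_task(aois, p[0], p[1]) == want_on:
            return p
    return np.array([0.0, 0.0])


def _plan_freeview(rng, duration_s, amp_mean, p_on, aois):
    """Fixation centroid sequence for freeview/social viewing.

    Each fixation's on-task membership is drawn Bernoulli(p_on) up front and
    the landing point is steered to realize it, so the on-task time fraction
    is unbiased; the saccade-amplitude target is honored whenever a
    direction with the requested membership is reachable.
    """
    pts = [np.array([0.0, 0.0])]
    t = 0.0
    while t < duration_s:
        p = pts[-1]
        want_on = rng.random() < p_on / 100.0
        amp = max(rng.normal(amp_mean, 0.15 * amp_mean), 1.0)
        thetas = rng.uniform(0, 2 * np.pi, size=40)
        cands = p[None, :] + amp * np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        inside = (np.abs(cands[:, 0]) < SCREEN_X) & (np.abs(cands[:, 1]) < SCREEN_Y)
        cands = cands[inside]
        if cands.size:
            on_mask = np.array([_on_task(aois, cx, cy) for cx, cy in cands])
            pool = cands[on_mask == want_on]
        else:
            pool = np.empty((0, 2))
        if pool.size:
            pts.append(pool[rng.integers(len(pool))])
        else:
            pts.append(_sample_with_membership(rng, aois, want_on))
        t += 0.2  # conservative budget; rendering stops at duration
    return pts


def _plan_reading(rng, duration_s, reg_rate_pct):
    """Left-to-right fixation sequence with leftward regressions.

    Regressions are scheduled by a renewal "debt" counter that accrues the
    target rate per step and fires when at least one unit of debt is owed
    and a leftward step stays on the line — so the long-run regression
    fraction equals the target even though edge-of-line steps are never
    regressive.
    """
    p_reg = reg_rate_pct / 100.0
    x, y = -11.0, 6.0
    pts = [np.array([x, y])]
    t = 0.0
    debt = 0.0
    trigger = rng.uniform(0.5, 1.5)
    while t < duration_s:
        if x > 11.0:           # line-return sweep (changes line, |dy| > 1)
            x = -11.0
            y = y - 1.5 if y > -6.0 else 6.0
        else:
            debt += p_reg
            back = max(rng.normal(1.8, 0.3), 1.0)
            if debt >= trigger and x - back >= -11.8:
                x -= back
                debt -= 1.0
                trigger = rng.uniform(0.5, 1.5)
            else:
                x += np.clip(rng.normal(2.0, 0.3), 1.2, 3.0)
        pts.append(np.array([x, y]))
        t += 0.2
    return pts


def synth_gaze(
    profile: ParticipantProfile,
    condition: str,
    task: str = "freeview",
    duration_s: float = 60.0,
    fs: float = 1200.0,
) -> GazeStream:
    """Render one gaze record realizing the profile's oculomotor targets."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if duration_s < 5:
        raise ValueError("duration must be at least 5 s")

    rng = np.random.default_rng(np.random.SeedSequence(
        [profile.seed, 505, hash((condition, task)) % (2**31)]))
    aois = default_aoi_layout(task)

    fix_mean = profile.target(condition, "fixation_ms") / 1000.0
    fix_sd = max(profile.target(condition, "fixation_ms") * 0.17, 1.0) / 1000.0
    mu, sigma = _lognormal_params(fix_mean, fix_sd)
    amp_mean = profile.target(condition, "saccade_amp_deg")
    p_on = profile.target(condition, "on_task_pct")
    ms_rate = profile.target(condition, "microsaccade_hz")
    blink_per_min = profile.target(condition, "blink_per_min")
    pupil_var = profile.target(condition, "pupil_var_mm2")

    if task == "reading":
        centroids = _plan_reading(rng, duration_s, profile.target(condition, "regression_pct"))
    else:
        centroids = _plan_freeview(rng, duration_s, amp_mean, p_on, aois)

    # blink probability per fixation cycle, correcting for blinks
    # lengthening the cycle: p = r(fix+sac) / (1 − r(blink − sac))
    r = blink_per_min / 60.0
    sac_s, blink_s = 0.035, 0.185
    p_blink = float(np.clip(r * (fix_mean + sac_s) / (1.0 - r * (blink_s - sac_s)),
                            0.0, 0.5))

    n_total = int(round(duration_s * fs))
    x = np.full(n_total, np.nan)
    y = np.full(n_total, np.nan)
    valid = np.zeros(n_total, dtype=bool)

    pos = 0
    for k, c in enumerate(centroids):
        if pos >= n_total:
            break
        # --- fixation ---
        dur = float(np.clip(rng.lognormal(mu, sigma), 0.08, 2.0))
        n_fix = min(int(round(dur * fs)), n_total - pos)
        drift_x = lfilter([_DRIFT_STEP], [1, -_DRIFT_RHO],
                          rng.standard_normal(n_fix))
        drift_y = lfilter([_DRIFT_STEP], [1, -_DRIFT_RHO],
                          rng.standard_normal(n_fix))
        fx = c[0] + drift_x
        fy = c[1] + drift_y
        # microsaccades: persistent small excursions
        n_ms = rng.poisson(ms_rate * dur)
        ms_n = max(int(_MS_DUR_S * fs), 2)
        for _ in range(n_ms):
            start = rng.integers(0, max(n_fix - ms_n, 1))
            amp = rng.uniform(0.3, 0.5)
            th = rng.uniform(0, 2 * np.pi)
            prof = (1 - np.cos(np.pi * np.arange(ms_n) / ms_n)) / 2.0
            fx[start:start + ms_n] += amp * np.cos(th) * prof[: n_fix - start]
            fy[start:start + ms_n] += amp * np.sin(th) * prof[: n_fix - start]
            fx[start + ms_n:] += amp * np.cos(th)
            fy[start + ms_n:] += amp * np.sin(th)
        x[pos:pos + n_fix] = fx
        y[pos:pos + n_fix] = fy
        valid[pos:pos + n_fix] = True
        pos += n_fix
        if pos >= n_total or k + 1 >= len(centroids):
            break
        # --- blink (masks the transition) or saccade ---
        if rng.random() < p_blink:
            n_blk = min(int(rng.uniform(0.12, 0.25) * fs), n_total - pos)
            pos += n_blk  # samples stay invalid/NaN
        else:
            nxt = centroids[k + 1]
            amp = float(np.hypot(*(nxt - c)))
            sac_dur = (21.0 + 2.2 * amp) / 1000.0
            n_sac = min(max(int(round(sac_dur * fs)), 2), n_total - pos)
            u = (1 - np.cos(np.pi * (np.arange(n_sac) + 1) / n_sac)) / 2.0
            x[pos:pos + n_sac] = c[0] + (nxt[0] - c[0]) * u
            y[pos:pos + n_sac] = c[1] + (nxt[1] - c[1]) * u
            valid[pos:pos + n_sac] = True
            pos += n_sac

    # pupil: smooth noise at the target variance around a 3.5 mm baseline
    white = rng.standard_normal(n_total)
    from scipy.signal import butter, filtfilt
    b, a = butter(2, 0.8 / (fs / 2.0))
    smooth = filtfilt(b, a, white)
    sd = smooth.std()
    pupil = 3.5 + smooth * (np.sqrt(pupil_var) / sd if sd > 0 else 0.0)
    pupil[~valid] = np.nan

    t = np.arange(n_total) / fs
    return GazeStream(t=t, x=x, y=y, pupil=pupil, valid=valid, fs=fs, aois=aois)
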