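"""Oculomotor event segmentation (I-VT) and gaze metrics.

I-VT (velocity-threshold identification): point-to-point gaze velocity is
obtained from Savitzky–Golay-differentiated positions (20 ms window, order
2 — raw two-point differences at 1200 Hz are noise-dominated); samples below
the velocity threshold (default 30°/s) form fixations, samples at or above
it form saccades. Validity-loss runs of at least 75 ms are blinks; shorter
losses are interpolated. Fixations shorter than the minimum duration
(default 60 ms) are merged into the preceding fixation when their centroids
lie within 0.5°, otherwise discarded — every valid sample ends up in exactly
one of {fixation, saccade, discard}.

Metric conventions:

* on-task proportion — fixation-time fraction whose centroid falls inside an
  AOI tagged ``on_task`` (half-open boundaries), as a percentage.
* reading regressions — inter-fixation steps with leftward x-displacement
  beyond a 0.5° dead-band, as a percentage of steps; steps with |Δy| > 1°
  are line-return sweeps, excluded by reading-research convention.
* microsaccades — within-fixation velocity excursions above a median-based
  threshold (λ = 6 × the robust median-SD estimator) with amplitude < 1°,
  counted per second of fixation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from neuroadapt.signals import AOI, GazeStream

FIX, SAC, BLINK, DISCARD = 1, 2, 3, 0


@dataclass
class FixationEvent:
    start: float
    end: float
    cx: float
    cy: float

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass
class SaccadeEvent:
    start: float
    end: float
    amplitude: float
    peak_velocity: float
    dx: float  # signed x-displacement (reading direction)


@dataclass
class BlinkEvent:
    start: float
    end: float


def _interp_invalid(t: np.ndarray, v: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = v.copy()
    if valid.all():
        return out
    out[~valid] = np.interp(t[~valid], t[valid], v[valid])
    return out


def gaze_velocity(gaze: GazeStream, window_ms: float = 20.0) -> np.ndarray:
    """Savitzky–Golay speed (deg/s); invalid spans are bridged by linear
    interpolation before differentiation (their samples are labeled
    separately and never enter fixation/saccade statistics)."""
    w = int(round(window_ms / 1000.0 * gaze.fs))
    w = max(w + (w % 2 == 0), 5)
    valid = gaze.valid
    if valid.sum() < 2:
        return np.zeros(gaze.n_samples)
    x = _interp_invalid(gaze.t, np.where(valid, gaze.x, np.nan), valid)
    y = _interp_invalid(gaze.t, np.where(valid, gaze.y, np.nan), valid)
    vx = savgol_filter(x, w, 2, deriv=1, delta=1.0 / gaze.fs)
    vy = savgol_filter(y, w, 2, deriv=1, delta=1.0 / gaze.fs)
    return np.hypot(vx, vy)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end_exclusive, label) runs of a label array."""
    edges = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], edges, [labels.size]])
    return [(int(bounds[i]), int(bounds[i + 1]), int(labels[bounds[i]]))
            for i in range(bounds.size - 1)]


def ivt_labels(
    gaze: GazeStream,
    vel_thresh: float = 30.0,
    min_fix_ms: float = 60.0,
    blink_min_ms: float = 75.0,
    merge_dist_deg: float = 0.5,
) -> np.ndarray:
    """Per-sample I-VT class labels (FIX/SAC/BLINK/DISCARD).

    Every valid sample receives exactly one label; the event lists returned
    by :func:`ivt_segment` are the run-length encoding of this array.
    """
    speed = gaze_velocity(gaze)
    labels = np.where(speed < vel_thresh, FIX, SAC).astype(np.int8)

    # blink labeling: invalid runs >= blink_min_ms; shorter ones stay
    # interpolated and keep their velocity-based label
    min_blink = int(blink_min_ms / 1000.0 * gaze.fs)
    for s, e, lab in _runs((~gaze.valid).astype(np.int8)):
        if lab == 1:
            labels[s:e] = BLINK if (e - s) >= min_blink else labels[s:e]

    min_fix = int(min_fix_ms / 1000.0 * gaze.fs)
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        fix_runs = [(s, e) for s, e, lab in runs if lab == FIX]
        for i, (s, e) in enumerate(fix_runs):
            if e - s >= min_fix:
                continue
            cx, cy = np.mean(gaze.x[s:e]), np.mean(gaze.y[s:e])
            merged = False
            if i > 0:
                ps, pe = fix_runs[i - 1]
                if pe - ps >= min_fix:
                    pcx, pcy = np.mean(gaze.x[ps:pe]), np.mean(gaze.y[ps:pe])
                    gap_ok = not np.any(labels[pe:s] == BLINK)
                    if gap_ok and np.hypot(cx - pcx, cy - pcy) < merge_dist_deg:
                        labels[pe:e] = FIX  # absorb gap + short run
                        merged = True
            if not merged:
                labels[s:e] = DISCARD
            changed = True
            break  # re-derive runs after each change
    return labels


def ivt_segment(
    gaze: GazeStream,
    vel_thresh: float = 30.0,
    min_fix_ms: float = 60.0,
    blink_min_ms: float = 75.0,
    merge_dist_deg: float = 0.5,
) -> tuple[list[FixationEvent], list[SaccadeEvent], list[BlinkEvent]]:
    """Segment a gaze stream into fixations, saccades, and blinks."""
    if gaze.valid.sum() < int(0.1 * gaze.fs):
        warnings.warn("fewer than 100 ms of valid samples", stacklevel=2)
        return [], [], []
    labels = ivt_labels(gaze, vel_thresh, min_fix_ms, blink_min_ms,
                        merge_dist_deg)
    speed = gaze_velocity(gaze)

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    blinks: list[BlinkEvent] = []
    dt = 1.0 / gaze.fs
    for s, e, lab in _runs(labels):
        t0, t1 = gaze.t[s], gaze.t[e - 1] + dt
        if lab == FIX:
            fixations.append(FixationEvent(
                start=t0, end=t1,
                cx=float(np.mean(gaze.x[s:e])), cy=float(np.mean(gaze.y[s:e]))))
        elif lab == SAC:
            dx = gaze.x[e - 1] - gaze.x[s]
            dy = gaze.y[e - 1] - gaze.y[s]
            saccades.append(SaccadeEvent(
                start=t0, end=t1, amplitude=float(np.hypot(dx, dy)),
                peak_velocity=float(np.max(speed[s:e])), dx=float(dx)))
        elif lab == BLINK:
            blinks.append(BlinkEvent(start=t0, end=t1))
    return fixations, saccades, blinks


def on_task_proportion(fixations: list[FixationEvent], aois: list[AOI]) -> float:
    """Percent of fixation time whose centroid lies in an on-task AOI."""
    if not aois:
        raise ValueError("AOI layout must be non-empty")
    total = sum(f.end - f.start for f in fixations)
    if total <= 0:
        raise ValueError("zero total fixation time")
    on = sum(f.end - f.start for f in fixations
             if any(a.contains(f.cx, f.cy) for a in aois if "on_task" in a.tags))
    return 100.0 * on / total


def regression_rate(fixations: list[FixationEvent], dead_band: float = 0.5,
                    line_break_dy: float = 1.0) -> float:
    """Percent of reading steps that move leftward beyond the dead-band."""
    if len(fixations) < 2:
        raise ValueError("need at least 2 fixations")
    steps = 0
    regressions = 0
    for a, b in zip(fixations[:-1], fixations[1:]):
        if abs(b.cy - a.cy) > line_break_dy:
            continue  # line-return sweep
        steps += 1
        if b.cx - a.cx < -dead_band:
            regressions += 1
    if steps == 0:
        return 0.0
    return 100.0 * regressions / steps


def microsaccade_rate(
    gaze: GazeStream,
    fixations: list[FixationEvent],
    lam: float = 6.0,
    amp_max_deg: float = 1.0,
    amp_min_deg: float = 0.1,
    min_samples: int = 6,
    vel_floor: float = 1.0,
) -> float:
    """Microsaccades per second of fixation time.

    Excursions must exceed the λ·σ velocity threshold for ≥ ``min_samples``
    samples and displace the eye by at least ``amp_min_deg`` (rejecting
    tremor tails) but less than ``amp_max_deg`` (true saccades are larger).
    """
    if not fixations:
        return 0.0
    speed = gaze_velocity(gaze)
    count = 0
    total_time = 0.0
    for f in fixations:
        s = int(round((f.start - gaze.t[0]) * gaze.fs))
        e = int(round((f.end - gaze.t[0]) * gaze.fs))
        v = speed[s:e]
        if v.size < 2 * min_samples:
            continue
        total_time += f.end - f.start
        sigma = np.sqrt(max(np.median(v**2) - np.median(v) ** 2, 0.0))
        # floor keeps numerical velocity noise below threshold on clean data
        thr = max(lam * sigma, vel_floor)
        above = v > thr
        for rs, re, lab in _runs(above.astype(np.int8)):
            if lab != 1 or re - rs < min_samples:
                continue
            seg = slice(s + rs, s + re)
            disp = np.hypot(gaze.x[seg] - gaze.x[s + rs],
                            gaze.y[seg] - gaze.y[s + rs])
            amp = float(np.nanmax(disp)) if disp.size else 0.0
            if amp_min_deg <= amp < amp_max_deg:
                count += 1
    if total_time <= 0:
        return 0.0
    return count / total_time


def pupil_variance(gaze: GazeStream) -> float:
    """Sample variance (mm²) of pupil diameter over valid samples."""
    p = gaze.pupil[gaze.valid & np.isfinite(gaze.pupil)]
    if p.size < 2:
        raise ValueError("need at least 2 valid pupil samples")
    return float(np.var(p, ddof=1))


def gaze_metrics(gaze: GazeStream, task: str = "freeview") -> dict[str, float]:
    """Full per-record gaze metric set."""
    fixations, saccades, blinks = ivt_segment(gaze)
    span = gaze.t[-1] - gaze.t[0] + 1.0 / gaze.fs
    out = {
        "fixation_count": float(len(fixations)),
        "fixation_ms": float(np.mean([f.duration_ms for f in fixations]))
        if fixations else float("nan"),
        "fixation_time_frac": sum(f.end - f.start for f in fixations) / span,
        "saccade_amp_deg": float(np.mean([s.amplitude for s in saccades]))
        if saccades else float("nan"),
        "on_task_pct": on_task_proportion(fixations, gaze.aois)
        if (fixations and gaze.aois) else float("nan"),
        "microsaccade_hz": microsaccade_rate(gaze, fixations),
        "blink_per_min": 60.0 * len(blinks) / span,
        "pupil_var_mm2": pupil_variance(gaze),
    }
    if task == "reading" and len(fixations) >= 2:
        out["regression_pct"] = regression_rate(fixations)
    return out
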