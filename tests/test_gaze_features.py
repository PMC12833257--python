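"""I-VT segmentation and gaze metrics, checked against a brute-force
per-sample oracle."""

import numpy as np
import pytest

from neuroadapt.gaze_features import (
    BLINK, DISCARD, FIX, SAC, _runs, gaze_velocity, ivt_labels, ivt_segment,
    microsaccade_rate, on_task_proportion, pupil_variance, regression_rate,
)
from neuroadapt.signals import AOI
from tests.conftest import make_gaze


def oracle_labels(gaze, vel_thresh=30.0, min_fix_ms=60.0, blink_min_ms=75.0,
                  merge_dist_deg=0.5):
    """Straight-line reimplementation: threshold the same velocity signal,
    mark long invalid runs as blinks, then resolve short fixations by a
    plain loop."""
    speed = gaze_velocity(gaze)
    labels = [FIX if v < vel_thresh else SAC for v in speed]
    n = len(labels)
    i = 0
    while i < n:  # invalid runs
        if not gaze.valid[i]:
            j = i
            while j < n and not gaze.valid[j]:
                j += 1
            if (j - i) >= int(blink_min_ms / 1000 * gaze.fs):
                for k in range(i, j):
                    labels[k] = BLINK
            i = j
        else:
            i += 1
    labels = np.array(labels, dtype=np.int8)
    min_fix = int(min_fix_ms / 1000 * gaze.fs)
    while True:
        runs = _runs(labels)
        fix_runs = [(s, e) for s, e, lab in runs if lab == FIX]
        short = [(idx, s, e) for idx, (s, e) in enumerate(fix_runs)
                 if e - s < min_fix]
        if not short:
            break
        idx, s, e = short[0]
        cx, cy = np.mean(gaze.x[s:e]), np.mean(gaze.y[s:e])
        merged = False
        if idx > 0:
            ps, pe = fix_runs[idx - 1]
            if pe - ps >= min_fix and not np.any(labels[pe:s] == BLINK):
                pcx, pcy = np.mean(gaze.x[ps:pe]), np.mean(gaze.y[ps:pe])
                if np.hypot(cx - pcx, cy - pcy) < merge_dist_deg:
                    labels[pe:e] = FIX
                    merged = True
        if not merged:
            labels[s:e] = DISCARD
    return labels


def two_point_gaze(fs=1200.0):
    """Two 400 ms stationary fixations joined by a 20 ms, 8 deg saccade."""
    n_fix = int(0.4 * fs)
    n_sac = int(0.02 * fs)
    x = np.concatenate([
        np.zeros(n_fix),
        8.0 * (1 - np.cos(np.pi * (np.arange(n_sac) + 1) / n_sac)) / 2,
        np.full(n_fix, 8.0),
    ])
    return make_gaze(x, np.zeros_like(x), fs=fs)


class TestIVT:
    def test_stationary_gaze_is_one_fixation(self):
        g = make_gaze(np.zeros(1200), np.zeros(1200))
        fx, sc, bl = ivt_segment(g)
        assert len(fx) == 1 and not sc and not bl
        assert fx[0].duration_ms == pytest.approx(1000.0, abs=5)

    def test_two_fixations_one_saccade(self):
        fx, sc, bl = ivt_segment(two_point_gaze())
        assert len(fx) == 2 and len(sc) == 1
        assert sc[0].amplitude == pytest.approx(8.0, abs=0.3)
        assert fx[1].cx - fx[0].cx == pytest.approx(8.0, abs=0.1)

    def test_short_validity_dip_is_not_a_blink(self):
        n = 1200
        valid = np.ones(n, dtype=bool)
        valid[500:554] = False  # 45 ms < 75 ms floor
        g = make_gaze(np.zeros(n), np.zeros(n), valid=valid)
        fx, _, bl = ivt_segment(g)
        assert not bl and len(fx) == 1

    def test_long_validity_loss_is_a_blink(self):
        n = 2400
        valid = np.ones(n, dtype=bool)
        valid[1000:1240] = False  # 200 ms
        g = make_gaze(np.zeros(n), np.zeros(n), valid=valid)
        _, _, bl = ivt_segment(g)
        assert len(bl) == 1
        assert (bl[0].end - bl[0].start) == pytest.approx(0.2, abs=0.01)

    def test_all_invalid_warns_empty(self):
        n = 600
        g = make_gaze(np.zeros(n), np.zeros(n),
                      valid=np.zeros(n, dtype=bool))
        with pytest.warns(UserWarning, match="valid"):
            fx, sc, bl = ivt_segment(g)
        assert not fx and not sc and not bl

    def test_labels_match_bruteforce_oracle(self, flat_profiles):
        from neuroadapt.synth import synth_gaze
        for cond, task in (("AR", "freeview"), ("traditional", "reading")):
            g = synth_gaze(flat_profiles["ADHD"], cond, task=task,
                           duration_s=10)
            assert np.array_equal(ivt_labels(g), oracle_labels(g))
        assert np.array_equal(ivt_labels(two_point_gaze()),
                              oracle_labels(two_point_gaze()))

    def test_segmentation_partitions_valid_span(self, flat_profiles):
        from neuroadapt.synth import synth_gaze
        g = synth_gaze(flat_profiles["TD"], "AR", duration_s=20)
        fx, sc, bl = ivt_segment(g)
        labels = ivt_labels(g)
        covered = (sum(f.end - f.start for f in fx)
                   + sum(s.end - s.start for s in sc)
                   + sum(b.end - b.start for b in bl)
                   + (labels == DISCARD).sum() / g.fs)
        assert covered == pytest.approx(g.n_samples / g.fs, abs=2 / g.fs)
        assert set(np.unique(labels[g.valid])) <= {FIX, SAC, DISCARD}


class TestOnTask:
    def test_all_inside_is_100(self):
        aois = [AOI("panel", -5, -5, 5, 5, ("on_task",))]
        fx, _, _ = ivt_segment(make_gaze(np.zeros(1200), np.zeros(1200),
                                         aois=aois))
        assert on_task_proportion(fx, aois) == 100.0

    def test_half_time_half_proportion(self):
        from neuroadapt.gaze_features import FixationEvent
        aois = [AOI("panel", -5, -5, 5, 5, ("on_task",))]
        fx = [FixationEvent(0, 1, 0, 0), FixationEvent(1, 2, 8, 8)]
        assert on_task_proportion(fx, aois) == pytest.approx(50.0)

    def test_zero_fixation_time_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            on_task_proportion([], [AOI("p", 0, 0, 1, 1, ("on_task",))])


class TestRegressions:
    def _seq(self, xs, y=0.0):
        from neuroadapt.gaze_features import FixationEvent
        return [FixationEvent(i, i + 0.2, x, y) for i, x in enumerate(xs)]

    def test_left_to_right_has_none(self):
        assert regression_rate(self._seq([1, 3, 5, 7])) == 0.0

    def test_one_in_three_steps(self):
        assert regression_rate(self._seq([1, 3, 2, 4])) == pytest.approx(
            100 / 3)

    def test_line_returns_excluded(self):
        from neuroadapt.gaze_features import FixationEvent
        fx = [FixationEvent(0, 1, 1, 0), FixationEvent(1, 2, 3, 0),
              FixationEvent(2, 3, -11, -1.5),  # line return: dy > 1
              FixationEvent(3, 4, -9, -1.5)]
        assert regression_rate(fx) == 0.0

    def test_single_fixation_rejected(self):
        with pytest.raises(ValueError, match="2 fixations"):
            regression_rate(self._seq([1.0]))


class TestMicrosaccades:
    def test_noiseless_fixation_has_rate_zero(self):
        g = make_gaze(np.zeros(2400), np.zeros(2400))
        fx, _, _ = ivt_segment(g)
        assert microsaccade_rate(g, fx) == 0.0

    def test_three_injected_excursions_in_two_seconds(self):
        fs = 1200.0
        n = int(2 * fs)
        x = np.zeros(n)
        n_ms = 30  # 25 ms raised-cosine, 0.3 deg
        for start in (400, 1100, 1800):
            prof = 0.3 * (1 - np.cos(np.pi * np.arange(n_ms) / n_ms)) / 2
            x[start:start + n_ms] += prof
            x[start + n_ms:] += 0.3
        g = make_gaze(x, np.zeros(n), fs=fs)
        fx, _, _ = ivt_segment(g)
        assert len(fx) == 1
        assert microsaccade_rate(g, fx) == pytest.approx(1.5, rel=0.05)


class TestPupil:
    def test_constant_pupil_zero_variance(self):
        g = make_gaze(np.zeros(600), np.zeros(600))
        assert pupil_variance(g) == 0.0

    def test_two_sample_variance(self):
        g = make_gaze(np.zeros(2), np.zeros(2),
                      pupil=np.array([3.0, 3.2]), fs=1200.0)
        assert pupil_variance(g) == pytest.approx(0.02)

    def test_blinks_excluded(self):
        n = 600
        valid = np.ones(n, dtype=bool)
        pupil = np.full(n, 3.5)
        pupil[100:200] = np.nan
        valid[100:200] = False
        g = make_gaze(np.zeros(n), np.zeros(n), valid=valid, pupil=pupil)
        assert pupil_variance(g) == 0.0

    def test_all_invalid_rejected(self):
        g = make_gaze(np.zeros(10), np.zeros(10),
                      valid=np.zeros(10, dtype=bool))
        with pytest.raises(ValueError, match="valid"):
            pupil_variance(g)
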