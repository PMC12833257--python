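"""Cardiac features: Pan–Tompkins R-peak detection, RR artifact correction,
and time-domain / frequency-domain / entropy HRV metrics.

The QRS detector follows the classical Pan–Tompkins stages — band-pass
5–15 Hz, differentiation, squaring, 150 ms moving-window integration, then
adaptive dual signal/noise thresholds with a 200 ms refractory period and
search-back at 0.5× threshold when an expected beat is missed. Detected
integration-peak locations are refined to the local maximum of the
band-passed signal.

HRV frequency analysis interpolates the tachogram to a uniform 4 Hz grid
with a cubic spline, linearly detrends, and applies Welch's periodogram
(256 s windows, 50% overlap; records shorter than one window fall back to a
single full-length periodogram). Bands: VLF 0.003–0.04, LF 0.04–0.15,
HF 0.15–0.4 Hz; LF/HF indexes sympathovagal balance.

Sample entropy is SampEn(m=2, r=0.2·SDNN) with template self-matches
excluded; :func:`sample_entropy_bruteforce` is the O(n²) reference
implementation and the vectorized :func:`sample_entropy` must agree with it
to 1e-10.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from neuroadapt.signals import ChannelTimeSeries, RRSeries

HRV_BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}


# ---------------------------------------------------------------- detection

def detect_rpeaks(ecg: ChannelTimeSeries) -> RRSeries:
    """Pan–Tompkins QRS detection on a single-channel ECG (fs ≥ 250 Hz)."""
    if len(ecg.labels) != 1:
        raise ValueError("expected a single-channel ECG")
    if ecg.fs < 250:
        raise ValueError("sampling rate must be at least 250 Hz")
    if ecg.duration < 5:
        raise ValueError("record must be at least 5 s")
    fs = ecg.fs
    x = ecg.data[0]
    if np.ptp(x) < 1e-12:
        warnings.warn("flat ECG signal: no beats detected", stacklevel=2)
        return RRSeries.from_peaks(np.array([]))

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(int(0.150 * fs), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    # candidate peaks of the integrated signal
    min_dist = int(0.200 * fs)  # refractory
    cand, _ = sps.find_peaks(mwi, distance=min_dist)
    if cand.size == 0:
        warnings.warn("no candidate peaks found", stacklevel=2)
        return RRSeries.from_peaks(np.array([]))

    # adaptive dual thresholds (signal/noise running estimates)
    spki = float(np.max(mwi[: int(2 * fs)]) * 0.5) if mwi.size else 0.0
    npki = float(np.mean(mwi[: int(2 * fs)]) * 0.5)
    peaks: list[int] = []
    rr_avg = None
    for idx in cand:
        pk = mwi[idx]
        thr1 = npki + 0.25 * (spki - npki)
        if pk > thr1:
            peaks.append(idx)
            spki = 0.125 * pk + 0.875 * spki
            if len(peaks) >= 2:
                rr = peaks[-1] - peaks[-2]
                rr_avg = rr if rr_avg is None else 0.125 * rr + 0.875 * rr_avg
        else:
            npki = 0.125 * pk + 0.875 * npki
        # search-back: if a beat is overdue, accept the best candidate above
        # half threshold inside the missed stretch
        if rr_avg is not None and peaks and idx - peaks[-1] > 1.66 * rr_avg:
            lo, hi = peaks[-1] + min_dist, idx
            seg = [c for c in cand if lo <= c < hi and mwi[c] > 0.5 * thr1]
            if seg:
                best = int(seg[int(np.argmax(mwi[seg]))])
                peaks.append(best)
                peaks.sort()
                spki = 0.25 * mwi[best] + 0.75 * spki

    # refine to local maxima of the band-passed signal (QRS alignment)
    half = int(0.075 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half, x.size)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    if refined.size >= 2:
        keep = np.concatenate([[True], np.diff(refined) > min_dist])
        refined = refined[keep]
    return RRSeries.from_peaks(refined / fs + ecg.start)


# --------------------------------------------------------------- correction

def correct_rr_artifacts(rr: RRSeries, thresh_s: float = 0.25,
                         window_beats: int = 11) -> RRSeries:
    """Replace intervals deviating from the local median by > ``thresh_s``.

    The local median uses an 11-beat centred window; flagged intervals are
    replaced by cubic interpolation through the surrounding clean beats.
    The number of corrections is recorded on the returned series.
    """
    if rr.rr_ms.size < 3:
        raise ValueError("need at least 3 intervals")
    import pandas as pd

    intervals = rr.rr_ms.copy()
    med = (pd.Series(intervals)
           .rolling(window_beats, center=True, min_periods=1)
           .median().to_numpy())
    bad = np.abs(intervals - med) > thresh_s * 1000.0
    if bad.all():
        raise ValueError("uncorrectable series: every interval flagged")
    if bad.any():
        idx = np.arange(intervals.size)
        spline = CubicSpline(idx[~bad], intervals[~bad])
        intervals[bad] = spline(idx[bad])
    out = RRSeries.from_intervals(intervals, t0=rr.peak_times[0])
    out.n_corrected = int(bad.sum())
    return out


# -------------------------------------------------------------- time domain

def hrv_time_domain(rr: RRSeries) -> dict[str, float]:
    """RMSSD, SDNN, pNN50, RR coefficient of variation, mean HR."""
    if rr.rr_ms.size < 2:
        raise ValueError("need at least 2 intervals")
    x = rr.rr_ms
    d = np.diff(x)
    mean_rr = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    return {
        "rmssd_ms": float(np.sqrt(np.mean(d**2))),
        "sdnn_ms": sdnn,
        "pnn50_pct": float(100.0 * np.mean(np.abs(d) > 50.0)),
        "rr_cv": sdnn / mean_rr,
        "mean_hr_bpm": 60000.0 / mean_rr,
    }


# --------------------------------------------------------- frequency domain

def hrv_freq_domain(rr: RRSeries, resample_hz: float = 4.0,
                    window_s: float = 256.0) -> dict[str, float]:
    """Welch band powers of the uniformly resampled, detrended tachogram."""
    if rr.span < 60:
        raise ValueError("record span must be at least 60 s")
    if rr.span < 120:
        warnings.warn("span < 120 s: LF estimates unreliable", stacklevel=2)
    # tachogram at interval midpoints, cubic spline to a uniform grid
    t_mid = (rr.peak_times[:-1] + rr.peak_times[1:]) / 2.0
    spline = CubicSpline(t_mid, rr.rr_ms)
    t_uni = np.arange(t_mid[0], t_mid[-1], 1.0 / resample_hz)
    x = sps.detrend(spline(t_uni), type="linear")

    nperseg = min(int(window_s * resample_hz), x.size)
    freqs, psd = sps.welch(x, fs=resample_hz, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    df = freqs[1] - freqs[0]
    out: dict[str, float] = {}
    for name, (lo, hi) in HRV_BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        out[f"{name}_ms2"] = float(np.sum(psd[mask]) * df)
    if out["hf_ms2"] <= 0:
        raise ValueError("zero HF power: LF/HF undefined")
    out["lf_hf"] = out["lf_ms2"] / out["hf_ms2"]
    return out


# ------------------------------------------------------------ sample entropy

def sample_entropy_bruteforce(x: np.ndarray, m: int = 2,
                              r: float | None = None,
                              r_frac: float = 0.2) -> float:
    """O(n²) reference SampEn with explicit template loops (oracle)."""
    x = np.asarray(x, float)
    n = x.size
    if r is None:
        r = r_frac * np.std(x, ddof=1)
    r = max(r, 1e-6 * abs(np.mean(x)))
    b_count = a_count = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b_count += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a_count += 1
    if b_count == 0 or a_count == 0:
        raise ValueError("undefined entropy: no template matches")
    return float(-np.log(a_count / b_count))


def sample_entropy(rr: RRSeries | np.ndarray, m: int = 2,
                   r_frac: float = 0.2) -> float:
    """Vectorized SampEn(m, r = r_frac·SDNN) on the RR series.

    Self-matches are excluded; ``r`` is floored at 1e-6·mean for
    near-constant series. Agrees with the brute-force oracle to 1e-10.
    """
    x = rr.rr_ms if isinstance(rr, RRSeries) else np.asarray(rr, float)
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 intervals for SampEn")
    r = max(r_frac * np.std(x, ddof=1), 1e-6 * abs(np.mean(x)))

    def count_pairs(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)  # (n-mm+1, mm)
        n_t = n - m  # use the same template count for both lengths
        emb = emb[:n_t]
        total = 0
        for i in range(n_t - 1):
            d = np.max(np.abs(emb[i + 1:] - emb[i]), axis=1)
            total += int(np.sum(d <= r))
        return total

    b_count = count_pairs(m)
    a_count = count_pairs(m + 1)
    if b_count == 0 or a_count == 0:
        raise ValueError("undefined entropy: no template matches")
    return float(-np.log(a_count / b_count))


def hrv_metrics(rr: RRSeries, with_entropy: bool = True) -> dict[str, float]:
    """All HRV metrics for one RR series (convenience aggregate)."""
    out = hrv_time_domain(rr)
    out.update(hrv_freq_domain(rr))
    if with_entropy and rr.rr_ms.size >= 50:
        try:
            out["sample_entropy"] = sample_entropy(rr)
        except ValueError:
            out["sample_entropy"] = float("nan")
    return out
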