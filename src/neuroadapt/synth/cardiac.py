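"""Synthetic RR tachograms and ECG traces.

The RR series is a sinusoid-plus-noise tachogram: mean RR plus one carrier
in the LF band (0.095 Hz), one in the HF band (0.275 Hz), a slow VLF drift
(0.01 Hz), and white per-beat noise. Carrier amplitudes are solved in closed
form so that (i) the spectrally analyzed LF/HF ratio and (ii) the RMSSD of
the generated series hit the profile targets jointly, accounting for the
noise power falling in each band:

    RMSSD² = 4·sin²(π·f_LF·T)·P_LF + 4·sin²(π·f_HF·T)·P_HF + 2·σ²
    (P_LF + N_LF) / (P_HF + N_HF) = LF/HF target

with ``P = A²/2`` the carrier power, ``T`` the mean beat period, and ``N``
the white-noise power landing in each analysis band.

The ECG trace is a template train: a Gaussian Q-R-S complex (~100 ms) plus
low, wide P and T waves centred at each R time, with optional additive white
noise at a stated SNR — enough structure to exercise QRS detection without
pretending to model cardiac electrophysiology.
"""

from __future__ import annotations

import warnings

import numpy as np

from neuroadapt.signals import ChannelTimeSeries, RRSeries
from neuroadapt.synth.profiles import ParticipantProfile

F_VLF, F_LF, F_HF = 0.01, 0.095, 0.275
_LF_BW, _HF_BW = 0.15 - 0.04, 0.40 - 0.15

# Mean heart rate per condition (bpm): task-related acceleration is ~8 bpm
# lower in the AR condition.
_MEAN_HR = {"traditional": 98.0, "AR": 90.0}


def solve_carrier_amplitudes(
    lf_hf_target: float, rmssd_target_ms: float, noise_sd_ms: float,
    mean_rr_ms: float,
) -> tuple[float, float]:
    """Return (A_LF, A_HF) in ms realizing the LF/HF and RMSSD targets."""
    T = mean_rr_ms / 1000.0
    s_l = np.sin(np.pi * F_LF * T) ** 2
    s_h = np.sin(np.pi * F_HF * T) ** 2
    # white-noise PSD in beat domain ~ 2*T*sigma^2 (one-sided), integrated
    # over each analysis band
    n_lf = _LF_BW * 2.0 * T * noise_sd_ms**2
    n_hf = _HF_BW * 2.0 * T * noise_sd_ms**2
    c = lf_hf_target * n_hf - n_lf
    budget = rmssd_target_ms**2 - 2.0 * noise_sd_ms**2
    if budget <= 0:
        raise ValueError("noise SD too large for the RMSSD target")
    y = (budget - 4.0 * s_l * c) / (4.0 * (s_l * lf_hf_target + s_h))
    y = max(y, 1e-9)
    x = max(lf_hf_target * y + c, 1e-9)
    return float(np.sqrt(2.0 * x)), float(np.sqrt(2.0 * y))


def synth_rr_from_params(
    mean_rr_ms: float,
    a_lf_ms: float,
    a_hf_ms: float,
    duration_s: float,
    seed: int = 0,
    a_vlf_ms: float = 0.0,
    noise_sd_ms: float = 0.0,
) -> RRSeries:
    """Low-level tachogram synthesis from explicit modulation amplitudes."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    phases = rng.uniform(0, 2 * np.pi, size=3)
    # 0.5 s lead-in so the first QRS complex is fully rendered in ECG traces
    times = [0.5]
    t = 0.5
    while t < duration_s:
        rr = (mean_rr_ms
              + a_vlf_ms * np.sin(2 * np.pi * F_VLF * t + phases[0])
              + a_lf_ms * np.sin(2 * np.pi * F_LF * t + phases[1])
              + a_hf_ms * np.sin(2 * np.pi * F_HF * t + phases[2]))
        if noise_sd_ms > 0:
            rr += noise_sd_ms * rng.standard_normal()
        rr = max(rr, 250.0)  # physiological floor
        t += rr / 1000.0
        times.append(t)
    return RRSeries.from_peaks(np.asarray(times))


def synth_rr(
    profile: ParticipantProfile, condition: str, duration_s: float = 360.0,
) -> RRSeries:
    """Panel-driven tachogram whose analyzed LF/HF, RMSSD, and mean HR match
    the profile's targets. Durations below 120 s are allowed but flagged
    (spectral targets need several LF cycles)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if duration_s < 120:
        warnings.warn("duration < 120 s: spectral LF/HF targets unreliable",
                      stacklevel=2)
    lf_hf = profile.target(condition, "lf_hf")
    rmssd = profile.target(condition, "rmssd_ms")
    rr_cv = profile.target(condition, "rr_cv")
    sampen = profile.target(condition, "sample_entropy")
    mean_rr = 60000.0 / _MEAN_HR[condition]

    # broadband-noise share of RMSSD² rises with the irregularity target
    nu = float(np.clip(0.15 + 0.30 * (sampen - 1.0), 0.05, 0.60))
    noise_sd = rmssd * np.sqrt(nu / 2.0)
    a_lf, a_hf = solve_carrier_amplitudes(lf_hf, rmssd, noise_sd, mean_rr)
    a_vlf = 25.0 * (rr_cv / 0.34)  # slow drift scaled by the group HRV-CV coefficient
    return synth_rr_from_params(
        mean_rr_ms=mean_rr, a_lf_ms=a_lf, a_hf_ms=a_hf, a_vlf_ms=a_vlf,
        noise_sd_ms=noise_sd, duration_s=duration_s,
        seed=profile.seed + {"traditional": 0, "AR": 1}[condition],
    )


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def synth_ecg_trace(
    rr: RRSeries, fs: float = 500.0, snr_db: float | None = None,
    amplitude_mv: float = 1.0, seed: int = 0,
) -> ChannelTimeSeries:
    """Lead-II-like single-channel trace with a QRS template at each R time."""
    if fs < 250:
        raise ValueError("ECG sampling rate must be at least 250 Hz")
    if rr.n_beats == 0:
        raise ValueError("empty RR series")
    t_end = rr.peak_times[-1] + 0.5
    n = int(np.ceil(t_end * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    # component: (offset s, width s, relative amplitude)
    waves = [(-0.180, 0.035, 0.10),   # P
             (-0.030, 0.008, -0.15),  # Q
             (0.0, 0.012, 1.00),      # R
             (0.030, 0.009, -0.20),   # S
             (0.220, 0.050, 0.25)]    # T
    for tp in rr.peak_times:
        lo = max(int((tp - 0.45) * fs), 0)
        hi = min(int((tp + 0.45) * fs), n)
        seg = t[lo:hi]
        for off, sig, amp in waves:
            x[lo:hi] += amplitude_mv * amp * _gauss(seg, tp + off, sig)
    if snr_db is not None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
        p_sig = float(np.mean(x**2))
        x = x + rng.standard_normal(n) * np.sqrt(p_sig / 10 ** (snr_db / 10.0))
    return ChannelTimeSeries(labels=["II"], fs=fs, data=x[None, :], units="mV")
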