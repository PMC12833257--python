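"""Synthetic EEG: band-limited Gaussian noise with controllable band powers,
alpha asymmetry, and frontal-temporal gamma coherence.

Each channel is a sum of independent band-limited Gaussian processes, one
per canonical band (delta 1–4, theta 4–8, alpha 8–12, beta 13–30, gamma
30–45 Hz), synthesized in the frequency domain so the signal variance —
hence the Welch band power — equals the target exactly up to estimator
variance. Two structured effects are layered on top:

* **Alpha asymmetry**: left-hemisphere alpha is scaled so that
  ``P_left = P_right * (1 + AI)`` for the target asymmetry index ``AI``.
* **Gamma coherence**: frontal and temporal channels share a common gamma
  source mixed with channel-private gamma noise. With shared-variance
  fraction ``a²`` the expected magnitude-squared coherence is ``a⁴``, so the
  mixing weight is solved in closed form as ``a² = sqrt(MSC_target)``.
"""

from __future__ import annotations

import numpy as np

from neuroadapt.signals import ChannelTimeSeries
from neuroadapt.synth.profiles import ParticipantProfile

DEFAULT_MONTAGE = ["Fz", "FCz", "Cz", "F3", "F4", "C3", "C4", "T7", "T8"]
LEFT_SITES = ("F3", "C3", "T7")
RIGHT_SITES = ("F4", "C4", "T8")
FRONTAL_SITES = ("Fz", "F3", "F4")
TEMPORAL_SITES = ("T7", "T8")

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


def band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float,
    power: float = 1.0,
) -> np.ndarray:
    """Gaussian noise whose spectrum is flat on [low, high) Hz and zero
    elsewhere, normalized to variance ``power``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = np.zeros(freqs.size, dtype=complex)
    mask = (freqs >= low) & (freqs < high)
    k = int(mask.sum())
    if k == 0:
        raise ValueError(f"band [{low}, {high}) contains no FFT bins at fs={fs}")
    spectrum[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    if sd == 0:
        return x
    return x * (np.sqrt(power) / sd)


def solve_coherence_weight(msc_target: float, m_a: int, m_b: int) -> float:
    """Shared-gamma variance fraction ``a²`` realizing a target MSC between
    the *averaged* signals of two site groups of sizes ``m_a`` and ``m_b``.

    Group averaging shrinks channel-private noise variance by 1/m while the
    common source is untouched, so the expected group-level MSC is

        MSC = a⁴ / ((a² + (1−a²)/m_a) · (a² + (1−a²)/m_b)),

    solved for ``a²`` by bisection (the map is monotone on [0, 1]).
    """
    msc_target = float(np.clip(msc_target, 0.0, 1.0))
    if msc_target in (0.0, 1.0):
        return msc_target

    def f(a2: float) -> float:
        return a2**2 / ((a2 + (1 - a2) / m_a) * (a2 + (1 - a2) / m_b))

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if f(mid) < msc_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def synth_eeg(
    profile: ParticipantProfile,
    condition: str,
    duration_s: float = 60.0,
    fs: float = 256.0,
    montage: list[str] | None = None,
    coherence_weight: float | None = None,
) -> ChannelTimeSeries:
    """Generate a multichannel EEG record realizing the profile's targets.

    Parameters
    ----------
    duration_s : float
        Record length, ≥ 10 s.
    fs : float
        Sampling rate, ≥ 200 Hz (≥ 2× the highest band edge).
    coherence_weight : float, optional
        Override of the shared-gamma variance fraction ``a²``; 0 makes
        frontal/temporal gamma fully independent. Default solves
        ``a² = sqrt(target MSC)`` from the profile.
    """
    if duration_s < 10:
        raise ValueError("duration must be at least 10 s")
    highest = max(h for _, h in BANDS.values())
    if fs < 2 * highest:
        raise ValueError(f"fs={fs} below 2x highest band edge ({highest} Hz)")
    montage = list(montage) if montage is not None else list(DEFAULT_MONTAGE)

    rng = np.random.default_rng(np.random.SeedSequence(
        [profile.seed, 101, hash(condition) % (2**31)]))
    n = int(round(duration_s * fs))

    band_targets = {b: profile.target(condition, b) for b in BANDS}
    asym = profile.target(condition, "alpha_asymmetry")
    msc = profile.target(condition, "gamma_coherence")
    n_front = sum(ch in FRONTAL_SITES for ch in montage)
    n_temp = sum(ch in TEMPORAL_SITES for ch in montage)
    if coherence_weight is None:
        a2 = solve_coherence_weight(msc, max(n_front, 1), max(n_temp, 1))
    else:
        a2 = float(np.clip(coherence_weight, 0.0, 1.0))

    # alpha targets: midline stays at the panel mean; right = mean,
    # left = mean * (1 + AI) so that (P_L - P_R)/P_R = AI.
    alpha_right = band_targets["alpha"]
    alpha_left = max(alpha_right * (1.0 + asym), 1e-6)

    shared_gamma = band_limited_noise(rng, n, fs, *BANDS["gamma"], power=1.0)

    data = np.zeros((len(montage), n))
    for i, ch in enumerate(montage):
        x = np.zeros(n)
        for band, (low, high) in BANDS.items():
            target = band_targets[band]
            if band == "alpha":
                if ch in LEFT_SITES:
                    target = alpha_left
                elif ch in RIGHT_SITES:
                    target = alpha_right
            if band == "gamma" and ch in FRONTAL_SITES + TEMPORAL_SITES:
                private = band_limited_noise(rng, n, fs, low, high, power=1.0)
                g = np.sqrt(a2) * shared_gamma + np.sqrt(1.0 - a2) * private
                sd = g.std()
                x += g * (np.sqrt(target) / sd if sd else 0.0)
            else:
                x += band_limited_noise(rng, n, fs, low, high, power=target)
        data[i] = x

    return ChannelTimeSeries(labels=montage, fs=fs, data=data, units="uV")
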