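import numpy as np
import pytest

from neuroadapt.signals import AOI, ChannelTimeSeries, GazeStream
from neuroadapt.signatures import SignaturePanel
from neuroadapt.synth import sample_profile


@pytest.fixture(scope="session")
def panel() -> SignaturePanel:
    return SignaturePanel.default()


@pytest.fixture(scope="session")
def flat_profiles(panel):
    """One profile per group pinned exactly at the group means."""
    return {g: sample_profile(g, panel, 1234, between_subject_scale=0.0)
            for g in ("ASD", "ADHD", "SLD", "TD")}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_sinusoid_ts(freq_hz: float, amp: float, fs: float = 256.0,
                     duration_s: float = 20.0,
                     labels: tuple[str, ...] = ("Fz",)) -> ChannelTimeSeries:
    t = np.arange(int(duration_s * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq_hz * t), (len(labels), 1))
    return ChannelTimeSeries(labels=list(labels), fs=fs, data=data)


def make_gaze(x: np.ndarray, y: np.ndarray, fs: float = 1200.0,
              valid: np.ndarray | None = None,
              pupil: np.ndarray | None = None,
              aois: list[AOI] | None = None) -> GazeStream:
    n = x.size
    return GazeStream(
        t=np.arange(n) / fs, x=x, y=y,
        pupil=pupil if pupil is not None else np.full(n, 3.5),
        valid=valid if valid is not None else np.ones(n, dtype=bool),
        fs=fs, aois=aois or [],
    )
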