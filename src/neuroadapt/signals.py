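"""Core in-memory containers for multimodal recordings and their text I/O.

Three substrates flow through the pipeline:

* :class:`ChannelTimeSeries` — a multichannel sampled signal (EEG in μV or a
  single-lead ECG in mV) with named channels and a uniform sampling rate.
* :class:`RRSeries` — ordered R-peak times and the inter-beat (RR) intervals
  derived from them; every HRV metric operates on this.
* :class:`GazeStream` — uniformly sampled binocular-averaged gaze samples
  (degrees of visual angle), pupil diameter, and a per-sample validity flag,
  with an optional layout of named areas of interest (AOIs).

On-disk interchange is plain delimited text plus JSON sidecars, so fixtures
stay human-readable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelTimeSeries",
    "RRSeries",
    "GazeStream",
    "AOI",
    "read_channel_timeseries",
    "read_gaze_stream",
]


@dataclass
class ChannelTimeSeries:
    """Multichannel uniformly sampled signal.

    Parameters
    ----------
    labels : list of str
        Unique channel names (10–10 positions for EEG, e.g. ``Fz``; ``II``
        for a Lead-II ECG).
    fs : float
        Sampling rate in Hz, > 0.
    data : ndarray, shape (n_channels, n_samples)
        Sample matrix; units are the caller's (μV for EEG, mV for ECG).
    start : float
        Time of the first sample in seconds.
    units : str
        Unit label carried through to file sidecars.
    """

    labels: list[str]
    fs: float
    data: np.ndarray
    start: float = 0.0
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present (have {self.labels})")
        return self.data[idx]

    def pick(self, labels: list[str]) -> "ChannelTimeSeries":
        rows = np.array([self.labels.index(l) for l in labels])
        return ChannelTimeSeries(
            labels=list(labels), fs=self.fs, data=self.data[rows].copy(),
            start=self.start, units=self.units,
        )

    def to_files(self, path: str | Path) -> None:
        """Write ``<path>.csv`` (header = labels, one row per sample) and a
        ``<path>.json`` sidecar with fs/units/start."""
        path = Path(path)
        pd.DataFrame(self.data.T, columns=self.labels).to_csv(
            path.with_suffix(".csv"), index=False, float_format="%.6g"
        )
        sidecar = {"fs": self.fs, "units": self.units, "start": self.start}
        path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_channel_timeseries(path: str | Path) -> ChannelTimeSeries:
    """Read the delimited matrix + JSON sidecar written by ``to_files``."""
    path = Path(path)
    frame = pd.read_csv(path.with_suffix(".csv"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ChannelTimeSeries(
        labels=list(frame.columns), fs=float(meta["fs"]),
        data=frame.to_numpy().T, start=float(meta.get("start", 0.0)),
        units=str(meta.get("units", "uV")),
    )


@dataclass
class RRSeries:
    """Strictly increasing R-peak times (s) and RR intervals (ms).

    The invariant ``rr_ms[i] == 1000 * (t[i+1] - t[i])`` is enforced at
    construction; build from peak times with :meth:`from_peaks`.
    """

    peak_times: np.ndarray
    rr_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_corrected: int = 0

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.ndim != 1:
            raise ValueError("peak times must be 1-D")
        if self.peak_times.size >= 2 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        derived = 1000.0 * np.diff(self.peak_times)
        if self.rr_ms is None:
            self.rr_ms = derived
        else:
            self.rr_ms = np.asarray(self.rr_ms, dtype=float)
            if not np.allclose(self.rr_ms, derived, atol=1e-6):
                raise ValueError("rr_ms inconsistent with peak times")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_peaks(cls, peak_times: np.ndarray, n_corrected: int = 0) -> "RRSeries":
        return cls(peak_times=np.asarray(peak_times, float), rr_ms=None,
                   n_corrected=n_corrected)

    @classmethod
    def from_intervals(cls, rr_ms: np.ndarray, t0: float = 0.0) -> "RRSeries":
        rr_ms = np.asarray(rr_ms, dtype=float)
        times = t0 + np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
        return cls(peak_times=times, rr_ms=None)

    @property
    def n_beats(self) -> int:
        return self.peak_times.size

    @property
    def span(self) -> float:
        if self.n_beats < 2:
            return 0.0
        return float(self.peak_times[-1] - self.peak_times[0])

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.peak_times}).to_csv(path, index=False,
                                                      float_format="%.6f")

    @classmethod
    def from_file(cls, path: str | Path) -> "RRSeries":
        return cls.from_peaks(pd.read_csv(path)["t_s"].to_numpy())


@dataclass(frozen=True)
class AOI:
    """Named rectangular area of interest in degrees; half-open boundaries
    ``[x0, x1) × [y0, y1)``; tags like ``on_task`` / ``social`` drive the
    attention metrics."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float
    tags: tuple[str, ...] = ()

    def contains(self, x: float, y: float) -> bool:
        return (self.x0 <= x < self.x1) and (self.y0 <= y < self.y1)


@dataclass
class GazeStream:
    """Uniformly sampled gaze record.

    ``x``/``y`` are degrees of visual angle (origin screen centre, +x
    rightward); ``pupil`` is diameter in mm; ``valid`` flags tracked samples
    (x/y are undefined where ``valid`` is False). Sampling is nominally
    1200 Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    fs: float = 1200.0
    aois: list[AOI] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.pupil = np.asarray(self.pupil, float)
        self.valid = np.asarray(self.valid, bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.pupil.size == self.valid.size == n):
            raise ValueError("gaze arrays must share one length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1.0 / self.fs):
                raise ValueError("sampling must be uniform within one period")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def to_files(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({
            "t": self.t, "x": self.x, "y": self.y,
            "pupil": self.pupil, "valid": self.valid.astype(int),
        }).to_csv(path.with_suffix(".csv"), index=False, float_format="%.5f")
        layout = [
            {"name": a.name, "x0": a.x0, "y0": a.y0, "x1": a.x1, "y1": a.y1,
             "tags": list(a.tags)}
            for a in self.aois
        ]
        path.with_suffix(".json").write_text(
            json.dumps({"fs": self.fs, "aois": layout})
        )


def read_gaze_stream(path: str | Path) -> GazeStream:
    path = Path(path)
    frame = pd.read_csv(path.with_suffix(".csv"))
    meta = json.loads(path.with_suffix(".json").read_text())
    aois = [
        AOI(name=a["name"], x0=a["x0"], y0=a["y0"], x1=a["x1"], y1=a["y1"],
            tags=tuple(a.get("tags", [])))
        for a in meta.get("aois", [])
    ]
    return GazeStream(
        t=frame["t"].to_numpy(), x=frame["x"].to_numpy(), y=frame["y"].to_numpy(),
        pupil=frame["pupil"].to_numpy(), valid=frame["valid"].to_numpy().astype(bool),
        fs=float(meta.get("fs", 1200.0)), aois=aois,
    )
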