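"""Raw accelerometer recordings and their conversion to uniform 100 Hz streams.

A pocket-worn smartphone logs tri-axial acceleration with irregular
timestamps.  Downstream gait-event detection needs two uniformly sampled
versions of the vertical axis: a *raw* stream (resampled, gravity-corrected,
orientation-corrected, otherwise untouched) used for nonlinear stride-time
measures, and a *filtered* stream (low-pass Butterworth) used for linear
measures and for the wavelet-based event search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "AccelRecording",
    "UniformSignal",
    "read_recording_csv",
    "resample_uniform",
    "correct_orientation_and_gravity",
    "lowpass_filter",
]


@dataclass
class AccelRecording:
    """Timestamped tri-axial acceleration stream.

    Parameters
    ----------
    t : array of float
        Sample timestamps in seconds, non-decreasing.
    ax, ay, az : array of float
        Acceleration along each device axis, m/s².
    vertical_axis : {'ax', 'ay', 'az'}
        The axis aligned with gravity / the long axis of the phone.  Only
        this axis is used by the pipeline; no rotation correction is applied.
    fs_nominal : float
        Advertised sampling rate in Hz (the actual spacing is irregular).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    vertical_axis: str = "az"
    fs_nominal: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValueError("t, ax, ay, az must have equal lengths")
        if n >= 2 and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.vertical_axis not in ("ax", "ay", "az"):
            raise ValueError(f"unknown vertical_axis {self.vertical_axis!r}")

    @property
    def vertical(self) -> np.ndarray:
        return getattr(self, self.vertical_axis)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t_s": self.t, "ax": self.ax, "ay": self.ay, "az": self.az}
        ).to_csv(path, index=False)


def read_recording_csv(path, vertical_axis: str = "az",
                       fs_nominal: float = 100.0) -> AccelRecording:
    """Read a recording CSV with columns ``t_s, ax, ay, az``."""
    df = pd.read_csv(path)
    missing = {"t_s", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"recording CSV {path} missing columns {sorted(missing)}")
    return AccelRecording(
        t=df["t_s"].to_numpy(),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        vertical_axis=vertical_axis,
        fs_nominal=fs_nominal,
    )


@dataclass
class UniformSignal:
    """One axis of acceleration on a uniform time grid.

    ``times[i] = t0 + i / fs``.  The ``stream`` tag records whether the
    signal is the raw or the low-pass-filtered variant.
    """

    fs: float
    a: np.ndarray
    stream: str = "raw"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.stream not in ("raw", "filtered"):
            raise ValueError(f"stream must be 'raw' or 'filtered', got {self.stream!r}")

    def __len__(self) -> int:
        return self.a.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.a.size) / self.fs


def _collapse_duplicate_timestamps(t: np.ndarray, v: np.ndarray):
    """Average values sharing an identical timestamp."""
    tu, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if tu.size == t.size:
        return t, v
    sums = np.zeros(tu.size)
    np.add.at(sums, inverse, v)
    return tu, sums / counts


def resample_uniform(rec: AccelRecording, fs: float = 100.0) -> UniformSignal:
    """Linearly interpolate the vertical axis onto a uniform ``fs`` grid.

    The grid runs from the first to the last timestamp.  Duplicate
    timestamps are collapsed to their mean value before interpolation.
    An input that is already on the grid is returned unchanged (linear
    interpolation is exact at the nodes).
    """
    t, v = _collapse_duplicate_timestamps(rec.t, rec.vertical)
    if t.size < 2:
        raise ValueError("need at least 2 distinct timestamps to resample")
    if t[-1] - t[0] < 1.0:
        raise ValueError("recording shorter than 1 s")
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    return UniformSignal(fs=fs, a=np.interp(grid, t, v), stream="raw", t0=float(t[0]))


def correct_orientation_and_gravity(sig: UniformSignal,
                                    invert: bool = True) -> UniformSignal:
    """Remove the gravity bias and undo an upside-down mounting.

    The gravity bias is estimated as the whole-recording mean of the
    vertical signal (robust to sensor calibration offset) and subtracted;
    the result is multiplied by −1 when ``invert`` is set, as when the
    phone sits pointing downwards in a front pocket.
    """
    if len(sig) == 0:
        raise ValueError("empty signal")
    a = sig.a - sig.a.mean()
    if invert:
        a = -a
    return replace(sig, a=a)


def lowpass_filter(sig: UniformSignal, cutoff: float = 16.0,
                   order: int = 4) -> UniformSignal:
    """Causal single-pass Butterworth low-pass; returns the filtered stream.

    The pass is deliberately single (phase-shifting) rather than
    forward-backward: the downstream raw-stream relocation step assumes the
    filtered events lag the raw signal by a few frames.
    """
    if cutoff >= sig.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {sig.fs / 2} Hz")
    b, a = sps.butter(order, cutoff, btype="low", fs=sig.fs)
    return replace(sig, a=sps.lfilter(b, a, sig.a), stream="filtered")
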