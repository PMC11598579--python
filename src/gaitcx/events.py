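"""Right-heel-contact detection from vertical acceleration.

The detector works on the filtered uniform stream and follows a six-step
wavelet procedure: (1) high-pass the signal at 0.1 Hz to remove drift,
(2) integrate to a vertical velocity, (3) differentiate the velocity with
a Gaussian continuous wavelet transform (scale 12 samples at 100 Hz),
which acts as a smoothed differentiator, (4) find the deep local minima of
the wavelet trace (separated by more than 0.8 s — the lower limit of a
healthy adult stride — and more negative than 40 % of the median of the
ten deepest minima), (5) chain each minimum forward to the next local
maximum of the trace, and (6) take the first local minimum of the
acceleration signal after that maximum as the right-heel contact.

Because the low-pass filter is causal, the filtered-stream events lag the
raw signal slightly; :func:`relocate_in_raw` starts three frames before
each filtered event and searches forward in the raw stream for the first
local minimum, giving the event series used for nonlinear measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .preprocess import UniformSignal

__all__ = [
    "HeelContactSeries",
    "CwtTrace",
    "local_minima",
    "local_maxima",
    "drift_highpass",
    "integrate_velocity",
    "cwt_differentiate",
    "find_candidate_minima",
    "chain_to_heel_contacts",
    "relocate_in_raw",
    "detect_heel_contacts",
]

log = logging.getLogger(__name__)

#: reference rate at which the wavelet scale is specified
_REFERENCE_FS = 100.0


@dataclass
class HeelContactSeries:
    """Ordered right-heel-contact events for one stream of one recording."""

    indices: np.ndarray     # 0-based sample indices, strictly increasing
    stream: str             # 'raw' | 'filtered'
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size >= 2 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("event indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.indices / self.fs

    @property
    def n_events(self) -> int:
        return self.indices.size


@dataclass
class CwtTrace:
    """Gaussian-CWT response of the velocity signal (same grid as input)."""

    c: np.ndarray
    scale: float            # in samples at the reference 100 Hz rate
    fs: float
    t0: float = 0.0
    wavelet: str = "gaussian-derivative"


def _filled_diff_signs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signs of successive differences, with zeros back-filled from the right.

    The back-fill makes a plateau inherit the slope that follows it, so a
    descent→plateau→ascent pattern registers its minimum at the plateau's
    first sample.
    """
    s = np.sign(np.diff(x))
    n = s.size
    pos = np.where(s != 0, np.arange(n), n)
    nxt = np.minimum.accumulate(pos[::-1])[::-1]
    filled = np.where(nxt < n, s[np.minimum(nxt, n - 1)], 0.0)
    return s, filled


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of local minima (strictly below both neighbours; plateaus
    report their first sample)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    s, filled = _filled_diff_signs(x)
    i = np.arange(1, x.size - 1)
    return i[(s[i - 1] < 0) & (filled[i] > 0)]


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima, mirroring :func:`local_minima`."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    s, filled = _filled_diff_signs(x)
    i = np.arange(1, x.size - 1)
    return i[(s[i - 1] > 0) & (filled[i] < 0)]


def drift_highpass(sig: UniformSignal, cutoff: float = 0.1,
                   order: int = 4) -> UniformSignal:
    """Causal Butterworth high-pass removing low-frequency drift."""
    b, a = sps.butter(order, cutoff, btype="high", fs=sig.fs)
    return replace(sig, a=sps.lfilter(b, a, sig.a))


def integrate_velocity(sig: UniformSignal) -> UniformSignal:
    """Cumulative trapezoidal integration of acceleration to velocity."""
    v = cumulative_trapezoid(sig.a, dx=1.0 / sig.fs, initial=0.0)
    return replace(sig, a=v)


def cwt_differentiate(vel: UniformSignal, scale: float = 12.0) -> CwtTrace:
    """Differentiate the velocity by convolution with a Gaussian-derivative
    wavelet.

    ``scale`` is the Gaussian standard deviation in samples at 100 Hz and
    is rescaled proportionally for other rates.  The sign convention makes
    the trace a smoothed version of the acceleration (a linear ramp in
    velocity yields a constant positive trace equal to its slope), so
    trace minima line up with the acceleration minima near heel contact.
    """
    fs = vel.fs
    sigma_samples = scale * fs / _REFERENCE_FS
    sigma_t = sigma_samples / fs
    half = int(np.ceil(4 * sigma_samples))
    if len(vel) < 2 * half + 1:
        raise ValueError(
            f"signal of {len(vel)} samples shorter than wavelet support "
            f"{2 * half + 1}")
    h = 1.0 / fs
    tt = np.arange(-half, half + 1) * h
    g = np.exp(-tt ** 2 / (2 * sigma_t ** 2)) / (sigma_t * np.sqrt(2 * np.pi))
    dg = -(tt / sigma_t ** 2) * g
    # normalize the first moment so the discrete kernel differentiates
    # linear signals exactly despite truncation and sampling
    dg /= -np.sum(dg * tt) * h
    c = np.convolve(vel.a, dg, mode="same") * h
    return CwtTrace(c=c, scale=scale, fs=fs, t0=vel.t0)


def find_candidate_minima(trace: CwtTrace, min_separation: float = 0.8,
                          threshold_fraction: float = 0.4) -> np.ndarray:
    """Deep, well-separated local minima of the CWT trace.

    The depth threshold is relative: ``threshold_fraction`` times the
    median of the ten most-negative local-minimum values, so detection is
    invariant to positive rescaling of the acceleration.  Minima closer
    than ``min_separation`` seconds are resolved greedily by depth.
    """
    mins = local_minima(trace.c)
    if mins.size < 10:
        raise ValueError(
            f"only {mins.size} local minima; need at least 10 to calibrate "
            "the detection threshold")
    vals = trace.c[mins]
    deepest10 = np.sort(vals)[:10]
    threshold = threshold_fraction * np.median(deepest10)
    passing = mins[vals < threshold]
    if passing.size == 0:
        return passing
    # greedy by depth: deepest first, reject anything within min_separation
    order = np.argsort(trace.c[passing])
    min_gap = int(round(min_separation * trace.fs))
    accepted: list[int] = []
    for idx in passing[order]:
        if all(abs(int(idx) - a) > min_gap for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def _enforce_spacing(indices: np.ndarray, min_gap: int) -> np.ndarray:
    """Drop the later event of any pair closer than ``min_gap`` samples."""
    kept: list[int] = []
    for i in indices:
        if not kept or i - kept[-1] > min_gap:
            kept.append(int(i))
        else:
            log.warning("dropping event at index %d: within minimum stride "
                        "separation of previous event", i)
    return np.array(kept, dtype=int)


def chain_to_heel_contacts(sig_filtered: UniformSignal, trace: CwtTrace,
                           candidates: np.ndarray,
                           min_separation: float = 0.8) -> HeelContactSeries:
    """Chain each candidate CWT minimum to a heel contact.

    For each candidate: forward to the next local maximum of the trace,
    then forward in the filtered acceleration to its first local minimum.
    Candidates that run off the end of the signal are dropped with a
    warning; duplicates collapse to a single event.
    """
    trace_maxima = local_maxima(trace.c)
    acc_minima = local_minima(sig_filtered.a)
    events: list[int] = []
    for cand in np.asarray(candidates, dtype=int):
        j = np.searchsorted(trace_maxima, cand, side="right")
        if j >= trace_maxima.size:
            log.warning("candidate at index %d: no CWT maximum before end of "
                        "signal; dropped", cand)
            continue
        k = np.searchsorted(acc_minima, trace_maxima[j], side="right")
        if k >= acc_minima.size:
            log.warning("candidate at index %d: no acceleration minimum before "
                        "end of signal; dropped", cand)
            continue
        events.append(int(acc_minima[k]))
    indices = np.unique(np.array(events, dtype=int))
    indices = _enforce_spacing(indices, int(round(min_separation * sig_filtered.fs)))
    return HeelContactSeries(indices=indices, stream="filtered",
                             fs=sig_filtered.fs, t0=sig_filtered.t0)


def relocate_in_raw(events_filtered: HeelContactSeries, sig_raw: UniformSignal,
                    offset_frames: int = 3,
                    min_separation: float = 0.8) -> HeelContactSeries:
    """Relocate filtered-stream events in the raw stream.

    Starts ``offset_frames`` before each filtered event (compensating the
    causal filter's delay) and searches forward for the first raw-signal
    local minimum.
    """
    raw_minima = local_minima(sig_raw.a)
    events: list[int] = []
    for i in events_filtered.indices:
        start = max(int(i) - offset_frames, 0)
        k = np.searchsorted(raw_minima, start, side="left")
        if k >= raw_minima.size:
            log.warning("filtered event at index %d: no raw minimum before end "
                        "of signal; dropped", i)
            continue
        events.append(int(raw_minima[k]))
    indices = np.unique(np.array(events, dtype=int))
    indices = _enforce_spacing(indices, int(round(min_separation * sig_raw.fs)))
    return HeelContactSeries(indices=indices, stream="raw",
                             fs=sig_raw.fs, t0=sig_raw.t0)


def detect_heel_contacts(sig_raw: UniformSignal, sig_filtered: UniformSignal,
                         *, hp_cutoff: float = 0.1, cwt_scale: float = 12.0,
                         min_separation: float = 0.8,
                         threshold_fraction: float = 0.4,
                         offset_frames: int = 3,
                         ) -> tuple[HeelContactSeries, HeelContactSeries]:
    """Full detection chain; returns (filtered-stream, raw-stream) events."""
    hp = drift_highpass(sig_filtered, cutoff=hp_cutoff)
    vel = integrate_velocity(hp)
    trace = cwt_differentiate(vel, scale=cwt_scale)
    candidates = find_candidate_minima(trace, min_separation=min_separation,
                                       threshold_fraction=threshold_fraction)
    ev_filtered = chain_to_heel_contacts(sig_filtered, trace, candidates,
                                         min_separation=min_separation)
    ev_raw = relocate_in_raw(ev_filtered, sig_raw, offset_frames=offset_frames,
                             min_separation=min_separation)
    return ev_filtered, ev_raw
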