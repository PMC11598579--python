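"""Synthetic stride-time series and gait-like acceleration recordings.

Free-living gait recordings are rarely shareable, so every stage of the
pipeline is validated against synthetic data with known ground truth:

* :func:`generate_isi` draws inter-stride-interval (ISI) series with a
  chosen statistical structure — i.i.d. Gaussian, exact fractional Gaussian
  noise (fGn) with a target Hurst exponent, a deterministic periodic
  pattern, or a periodic/random mixture.  Healthy adult walking shows
  stride times around 1.12 s with an SD near 0.04 s and strong long-range
  correlation (Hurst ≈ 0.9), which are the defaults here.
* :func:`generate_recording` turns ISI series into a pocket-phone-like
  vertical acceleration signal whose first post-maximum local minimum falls
  exactly at each right-heel contact, with gravity offset, optional
  upside-down orientation, timestamp jitter, sensor noise and non-walking
  gaps — returning the true event times and bout spans alongside.

The per-stride waveform is parametric (smooth windowed bumps plus a sharp
contact transient), not a biomechanical simulation: what matters for
testing the detector is the detectability contract, i.e. a local maximum
shortly before each contact followed by a sharp local minimum at the
contact itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import AccelRecording

__all__ = [
    "IsiGroundTruth",
    "SyntheticRecording",
    "fractional_gaussian_noise",
    "generate_isi",
    "generate_recording",
    "waveform_amplitude",
    "write_recording",
]

#: stride times are clipped below at this floor (s); half the 0.8 s
#: minimum healthy stride time used by the detector's separation rule,
#: so clipping can never produce a rule-violating series by accident.
CLIP_FLOOR_S = 0.4

# Per-stride waveform shape (m/s²; dip in phase fractions of the stride,
# spike/trough in seconds relative to the contact).  Chosen so that, after
# the detector's ~0.12 s wavelet smoothing, the broad mid-stance dip is by
# far the deepest trace minimum (the narrow contact features smooth almost
# away), the net smoothed spike-minus-trough residual peaks shortly before
# the contact (giving the trace maximum the chain searches for), and the
# acceleration descends steeply from the spike top into the trough with no
# flat region where sensor noise could fake an early local minimum.  All
# components have zero slope at the contact, so every true contact is an
# exact local minimum of the analytic waveform.
_MIDSTANCE_AMP = 4.0
_DIP_LO, _DIP_HI = 0.45, 0.9
_SPIKE_AMP = 10.0
_SPIKE_HALFWIDTH_S = 0.05
_SPIKE_LEAD_S = 0.065
_TROUGH_AMP = 8.0
_TROUGH_HALFWIDTH_S = 0.06

# Named RNG sub-streams, one per stochastic operation.
_STREAM_ISI = 1
_STREAM_RECORDING = 2


def _rng(seed: int | None, stream: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(stream,)))


@dataclass
class IsiGroundTruth:
    """A generated inter-stride-interval series with its generating model."""

    values: np.ndarray          # seconds per stride
    model: str                  # white | fgn | periodic | mix
    mean_s: float
    sd_s: float
    hurst: float | None = None  # fgn only
    seed: int | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("all stride times must be positive")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class SyntheticRecording:
    """A generated recording together with its ground truth."""

    accel: AccelRecording
    true_rhc_times: np.ndarray              # right-heel contacts, seconds
    true_bout_spans: list[tuple[float, float]]
    isi_truth: list[IsiGroundTruth]

    def __post_init__(self) -> None:
        self.true_rhc_times = np.asarray(self.true_rhc_times, dtype=float)
        if np.any(np.diff(self.true_rhc_times) <= 0):
            raise ValueError("true_rhc_times must be strictly increasing")


def fractional_gaussian_noise(n: int, hurst: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact unit-variance fGn via circulant embedding (Davies–Harte).

    The target autocovariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})
    is embedded in a circulant matrix whose eigenvalues are obtained by
    FFT; they are non-negative for fGn, so the construction is exact — no
    spectral approximation bias, which matters when the series feeds
    detrended fluctuation analysis.
    """
    if not (0.0 < hurst <= 1.0):
        raise ValueError(f"hurst must be in (0, 1], got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return rng.standard_normal(1)
    h2 = 2.0 * hurst
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)
    m = 2 * (n - 1)
    c = np.concatenate([gamma, gamma[n - 2:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise RuntimeError("circulant embedding produced negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal()
    w[n - 1] = np.sqrt(lam[n - 1]) * rng.standard_normal()
    j = np.arange(1, n - 1)
    if j.size:
        u = rng.standard_normal(j.size)
        v = rng.standard_normal(j.size)
        w[j] = np.sqrt(lam[j] / 2.0) * (u + 1j * v)
        w[m - j] = np.conj(w[j])
    x = np.fft.fft(w) / np.sqrt(m)
    return np.ascontiguousarray(x[:n].real)


def generate_isi(model: str, n: int, mean_s: float = 1.12, sd_s: float = 0.04,
                 hurst: float = 0.9, seed: int | None = None,
                 pattern=None, mix_prob: float = 0.5) -> IsiGroundTruth:
    """Generate ``n`` positive stride times with known structure.

    Parameters
    ----------
    model : {'white', 'fgn', 'periodic', 'mix'}
        ``white`` — i.i.d. Gaussian; ``fgn`` — exact fractional Gaussian
        noise with Hurst exponent ``hurst``; ``periodic`` — a deterministic
        repetition of ``pattern`` (default alternating mean ∓ sd); ``mix``
        — each stride taken from the random model with probability
        ``mix_prob``, otherwise from the periodic pattern.
    mean_s, sd_s : float
        Target mean and SD of the stride times, seconds.

    Values are clipped below at 0.4 s; the clip count is reported on the
    result.  Parameters for which more than 1 % of draws would clip are
    rejected as unusable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd_s < 0:
        raise ValueError("sd_s must be >= 0")
    rng = _rng(seed, _STREAM_ISI)

    if model in ("white", "fgn") and sd_s > 0:
        p_clip = norm.cdf((CLIP_FLOOR_S - mean_s) / sd_s)
        if p_clip > 0.01:
            raise ValueError(
                f"sd_s={sd_s} would clip {100 * p_clip:.1f}% of draws at the "
                f"{CLIP_FLOOR_S} s floor; parameters unusable")

    if model == "white":
        values = mean_s + sd_s * rng.standard_normal(n)
    elif model == "fgn":
        values = mean_s + sd_s * fractional_gaussian_noise(n, hurst, rng)
    elif model == "periodic":
        pat = np.asarray(pattern if pattern is not None
                         else [mean_s - sd_s, mean_s + sd_s], dtype=float)
        values = np.tile(pat, n // pat.size + 1)[:n]
    elif model == "mix":
        pat = np.asarray(pattern if pattern is not None
                         else [mean_s - sd_s, mean_s + sd_s], dtype=float)
        values = np.tile(pat, n // pat.size + 1)[:n].copy()
        take_random = rng.random(n) < mix_prob
        values[take_random] = mean_s + sd_s * rng.standard_normal(take_random.sum())
    else:
        raise ValueError(f"unknown model {model!r}")

    n_clipped = int(np.sum(values < CLIP_FLOOR_S))
    if n_clipped:
        warnings.warn(f"{n_clipped} stride time(s) clipped at {CLIP_FLOOR_S} s")
        values = np.maximum(values, CLIP_FLOOR_S)

    return IsiGroundTruth(values=values, model=model, mean_s=mean_s, sd_s=sd_s,
                          hurst=hurst if model == "fgn" else None,
                          seed=seed, n_clipped=n_clipped)


def _sin2_window(phi: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """sin² bump on [lo, hi] of unit height, zero value and slope at the edges."""
    out = np.zeros_like(phi)
    inside = (phi >= lo) & (phi <= hi)
    out[inside] = np.sin(np.pi * (phi[inside] - lo) / (hi - lo)) ** 2
    return out


def _cos2_bumps(t: np.ndarray, centres: np.ndarray, amp: float,
                halfwidth: float) -> np.ndarray:
    """Sum of cos² bumps of height ``amp`` at each centre (zero slope and
    value at the support edges and zero slope at the centre)."""
    out = np.zeros_like(t)
    k = np.clip(np.searchsorted(centres, t), 0, centres.size - 1)
    d = np.minimum(np.abs(t - centres[k]),
                   np.abs(t - centres[np.maximum(k - 1, 0)]))
    hit = d < halfwidth
    out[hit] = amp * np.cos(np.pi * d[hit] / (2 * halfwidth)) ** 2
    return out


def waveform_vertical(t: np.ndarray, bout_contacts: list[np.ndarray]) -> np.ndarray:
    """Noise- and gravity-free vertical acceleration at arbitrary times.

    Per stride (contact-to-contact), in stride phase φ, a broad mid-stance
    dip (−sin² window on φ∈[0.45, 0.9]) whose rising limb runs directly
    into the contact features; per contact, a sharp positive cos² spike
    65 ms before the contact and a negative cos² trough centred exactly on
    it — the classic pre-heel-strike peak followed by the heel-contact
    minimum.  Each bout additionally gets one lead-in mid-stance dip
    before its first contact, so the first contact is detectable by the
    same min→max→minimum chain as every other.
    """
    t = np.asarray(t, dtype=float)
    a = np.zeros_like(t)
    for contacts in bout_contacts:
        contacts = np.asarray(contacts, dtype=float)
        if contacts.size < 2:
            raise ValueError("each bout needs at least 2 contacts")
        isi = np.diff(contacts)
        # stride edges including the lead-in stride
        edges = np.concatenate([[contacts[0] - isi[0]], contacts])
        durs = np.concatenate([[isi[0]], isi])
        in_bout = (t >= edges[0]) & (t < edges[-1])
        if np.any(in_bout):
            tb = t[in_bout]
            j = np.clip(np.searchsorted(edges, tb, side="right") - 1, 0, durs.size - 1)
            phi = (tb - edges[j]) / durs[j]
            a[in_bout] -= _MIDSTANCE_AMP * _sin2_window(phi, _DIP_LO, _DIP_HI)
        a += _cos2_bumps(t, contacts - _SPIKE_LEAD_S, _SPIKE_AMP,
                         _SPIKE_HALFWIDTH_S)
        a -= _cos2_bumps(t, contacts, _TROUGH_AMP, _TROUGH_HALFWIDTH_S)
    return a


def waveform_amplitude(stride_s: float = 1.12) -> float:
    """Peak |vertical acceleration| of the noise-free waveform (m/s²).

    Useful for expressing sensor-noise levels relative to the signal.
    """
    contacts = np.arange(6) * stride_s + 2 * stride_s
    t = np.arange(contacts[0] - stride_s, contacts[-1], 1e-3)
    return float(np.max(np.abs(waveform_vertical(t, [contacts]))))


def generate_recording(bout_isis: list[IsiGroundTruth], gap_s=(),
                       fs_nominal: float = 100.0,
                       timestamp_jitter_sd: float = 0.001,
                       gravity: float = 9.81, invert: bool = True,
                       noise_sd: float = 0.05, seed: int | None = None,
                       lead_s: float = 2.0, tail_s: float = 0.5,
                       ) -> SyntheticRecording:
    """Build a recording from one or more ISI series separated by gaps.

    ``gap_s[i]`` is the time between the last contact of bout ``i`` and the
    first contact of bout ``i+1`` and must exceed 1.8 s (the bout-splitting
    rule) or the ground-truth bouts would merge.  Each ISI series of length
    n produces n+1 contacts.  Timestamps are nominally 1/fs apart with
    additive Gaussian jitter; white sensor noise of ``noise_sd`` is added
    to all three axes; ``gravity`` is added to the vertical axis and the
    whole signal is multiplied by −1 when ``invert`` is set.
    """
    gap_s = list(gap_s)
    if len(gap_s) != max(len(bout_isis) - 1, 0):
        raise ValueError("need exactly len(bout_isis) - 1 gaps")
    if any(g <= 1.8 for g in gap_s):
        raise ValueError("all gaps must exceed 1.8 s, or bouts would merge")
    if fs_nominal <= 0:
        raise ValueError("fs_nominal must be positive")
    rng = _rng(seed, _STREAM_RECORDING)

    bout_contacts: list[np.ndarray] = []
    t_cursor = lead_s
    for b, isi in enumerate(bout_isis):
        if b > 0:
            t_cursor += gap_s[b - 1]
        else:
            t_cursor += float(isi.values[0])  # room for the lead-in stride
        contacts = t_cursor + np.concatenate([[0.0], np.cumsum(isi.values)])
        bout_contacts.append(contacts)
        t_cursor = contacts[-1]

    t_end = t_cursor + tail_s
    nominal = np.arange(0.0, t_end, 1.0 / fs_nominal)
    if timestamp_jitter_sd > 0:
        t = np.sort(nominal + rng.normal(0.0, timestamp_jitter_sd, nominal.size))
        t = np.unique(t)
    else:
        t = nominal

    az = waveform_vertical(t, bout_contacts)
    if noise_sd > 0:
        az = az + rng.normal(0.0, noise_sd, t.size)
        ax = rng.normal(0.0, noise_sd, t.size)
        ay = rng.normal(0.0, noise_sd, t.size)
    else:
        ax = np.zeros_like(t)
        ay = np.zeros_like(t)
    az = az + gravity
    if invert:
        az, ax, ay = -az, -ax, -ay

    accel = AccelRecording(t=t, ax=ax, ay=ay, az=az,
                           vertical_axis="az", fs_nominal=fs_nominal)
    return SyntheticRecording(
        accel=accel,
        true_rhc_times=np.concatenate(bout_contacts),
        true_bout_spans=[(float(c[0]), float(c[-1])) for c in bout_contacts],
        isi_truth=list(bout_isis),
    )


def write_recording(rec: SyntheticRecording, outdir, prefix: str = "recording") -> dict:
    """Write the recording CSV plus ground-truth sidecars; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "recording": outdir / f"{prefix}.csv",
        "events": outdir / f"{prefix}_true_events.csv",
        "meta": outdir / f"{prefix}_truth.json",
    }
    rec.accel.to_csv(paths["recording"])
    pd.DataFrame({"t_s": rec.true_rhc_times}).to_csv(paths["events"], index=False)
    meta = {
        "bout_spans": rec.true_bout_spans,
        "bouts": [
            {"model": g.model, "mean_s": g.mean_s, "sd_s": g.sd_s,
             "hurst": g.hurst, "seed": g.seed, "n": g.n,
             "n_clipped": g.n_clipped, "values": g.values.tolist()}
            for g in rec.isi_truth
        ],
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths
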