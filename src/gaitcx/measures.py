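"""Linear and nonlinear stride-time variability measures.

Linear measures (mean stride time, SD, coefficient of variation) describe
the magnitude of variability; nonlinear measures describe its temporal
structure:

* **DFA / FSI** — detrended fluctuation analysis of the ISI series over
  box sizes 10–40 strides.  The log–log slope α (the fractal scaling
  index) is ≈0.5 for uncorrelated noise and approaches 1 for strongly
  persistent fluctuations.
* **ApEn / SaEn** — approximate and sample entropy with template length
  m = 2 and tolerance r = 0.15 × SD, Chebyshev distance.  ApEn includes
  self-matches (Pincus); SaEn excludes them (Richman–Moorman) and is
  exactly 0 for a strictly periodic series.
* **MSE / CI** — sample entropy of coarse-grained (window-averaged)
  series at scales 1–4, with r held fixed from the scale-1 series; the
  complexity index is the trapezoidal area under the SaEn-versus-scale
  curve.

Eligibility conventions: linear measures need at least 20 strides,
DFA/ApEn/SaEn more than 255 strides, and MSE/CI exactly 800 strides
(the first 800 of a participant's longest bout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bouts import WalkingBout

__all__ = [
    "EntropyParams",
    "DfaResult",
    "MseResult",
    "MeasureSet",
    "linear_measures",
    "dfa",
    "apen",
    "saen",
    "coarse_grain",
    "mse",
    "complexity_index",
]

MIN_LINEAR_STRIDES = 20       # ">19"
MIN_NONLINEAR_STRIDES = 256   # ">255"
MSE_REQUIRED_STRIDES = 800


@dataclass
class EntropyParams:
    """Template length m and similarity tolerance r for ApEn/SaEn."""

    m: int = 2
    r_fraction: float = 0.15
    r: float = 0.0              # seconds; r_fraction × SD of the series

    @classmethod
    def from_series(cls, x, m: int = 2, r_fraction: float = 0.15) -> "EntropyParams":
        x = np.asarray(x, dtype=float)
        r = r_fraction * float(np.std(x, ddof=1))
        if r <= 0:
            raise ValueError("zero-variance series: tolerance r would be 0")
        return cls(m=m, r_fraction=r_fraction, r=r)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class DfaResult:
    """DFA fit: the log–log slope alpha is the fractal scaling index."""

    alpha: float
    box_sizes: np.ndarray
    fluctuation: np.ndarray     # mean per-box RMS at each box size
    fit_intercept: float


@dataclass
class MseResult:
    """Sample entropy per coarse-graining scale, plus the shared tolerance."""

    scales: tuple
    values: dict                # scale -> SaEn (or None if undefined)
    lengths: dict               # scale -> coarse-grained series length
    params: EntropyParams


@dataclass
class MeasureSet:
    """Per-participant measures with eligibility flags.

    ``eligibility`` maps each measure name to ``None`` when the measure was
    computed, or to a human-readable reason it is null.
    """

    participant_id: str | None = None
    xisi: float | None = None       # mean stride time, s
    sd: float | None = None         # stride-time SD, s
    cov: float | None = None        # coefficient of variation, %
    fsi: float | None = None
    apen: float | None = None
    saen: float | None = None
    mse: dict = field(default_factory=dict)     # scale -> SaEn
    ci: float | None = None
    spd: float | None = None        # strides
    enhl: float | None = None       # strides
    eligibility: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "xISI_s": self.xisi, "SD_s": self.sd, "COV_pct": self.cov,
            "FSI": self.fsi, "ApEn": self.apen, "SaEn": self.saen,
        }
        for tau in sorted(self.mse):
            d[f"SaEn_scale{tau}"] = self.mse[tau]
        d["CI"] = self.ci
        d["SPD_strides"] = self.spd
        d["EnHL_strides"] = self.enhl
        return d


def _as_series(x) -> np.ndarray:
    if isinstance(x, WalkingBout):
        x = x.isi
    return np.asarray(x, dtype=float)


def linear_measures(bout) -> tuple[float, float, float]:
    """Mean stride time (s), sample SD (s) and COV (%) of a bout."""
    x = _as_series(bout)
    if x.size < MIN_LINEAR_STRIDES:
        raise ValueError(f"bout has {x.size} strides; linear measures need "
                         f">= {MIN_LINEAR_STRIDES}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return mean, sd, 100.0 * sd / mean


def dfa(x, box_min: int = 10, box_max: int = 40,
        min_length: int = MIN_NONLINEAR_STRIDES) -> DfaResult:
    """Detrended fluctuation analysis over integer box sizes.

    The series is mean-centred and cumulatively summed to a profile; for
    each box size n the profile is cut into ⌊N/n⌋ non-overlapping boxes
    from the start (the tail remainder is discarded), each box is linearly
    detrended by least squares, the RMS of the residuals is taken per box
    and averaged across boxes; alpha is the OLS slope of log10(mean RMS)
    on log10(n).
    """
    x = _as_series(x)
    n_samp = x.size
    if n_samp < min_length:
        raise ValueError(f"series of {n_samp} too short for DFA "
                         f"(needs >= {min_length})")
    profile = np.cumsum(x - x.mean())
    box_sizes = np.arange(box_min, box_max + 1)
    fluct = np.empty(box_sizes.size)
    for i, n in enumerate(box_sizes):
        k = n_samp // n
        z = profile[:k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        t_c = t - t.mean()
        denom = np.dot(t_c, t_c)
        slope = z @ t_c / denom
        resid = z - z.mean(axis=1, keepdims=True) - slope[:, None] * t_c
        rms = np.sqrt(np.mean(resid ** 2, axis=1))
        fluct[i] = rms.mean()
    if np.any(fluct <= 0):
        raise ValueError("zero fluctuation: series has no variance at some box size")
    coeffs = np.polyfit(np.log10(box_sizes), np.log10(fluct), 1)
    return DfaResult(alpha=float(coeffs[0]), box_sizes=box_sizes,
                     fluctuation=fluct, fit_intercept=float(coeffs[1]))


def _chebyshev_match(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Boolean matrix of length-m template matches (Chebyshev distance <= r).

    Entry (i, j) is True when templates starting at i and j match; shape
    (N-m+1, N-m+1).
    """
    n = x.size
    d = np.abs(x[:, None] - x[None, :])
    size = n - m + 1
    dm = d[:size, :size].copy()
    for k in range(1, m):
        np.maximum(dm, d[k:k + size, k:k + size], out=dm)
    return dm <= r


def apen(x, params: EntropyParams) -> float:
    """Approximate entropy (Pincus), self-matches included.

    ApEn = Φ_m − Φ_{m+1}, where Φ_m is the mean over templates of the log
    relative frequency of length-m matches within tolerance r.
    """
    x = _as_series(x)
    m, r = params.m, params.r
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if x.size < m + 2:
        raise ValueError("series too short for the requested template length")

    def phi(mm: int) -> float:
        match = _chebyshev_match(x, mm, r)
        c = match.sum(axis=1) / match.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def saen(x, params: EntropyParams) -> float | None:
    """Sample entropy (Richman–Moorman), self-matches excluded.

    SaEn = −ln(A/B) where B counts length-m template pairs within r and A
    counts length-(m+1) pairs, both over the same N−m template start
    points.  Returns ``None`` with a warning when A or B is zero (the
    statistic is undefined, never silently zero).
    """
    x = _as_series(x)
    m, r = params.m, params.r
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if x.size < m + 2:
        raise ValueError("series too short for the requested template length")
    n_templates = x.size - m
    match_m = _chebyshev_match(x, m, r)[:n_templates, :n_templates]
    match_m1 = _chebyshev_match(x, m + 1, r)
    b = (match_m.sum() - n_templates) / 2.0
    a = (match_m1.sum() - n_templates) / 2.0
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined: no template matches at "
                      f"length {m + 1 if a == 0 else m}")
        return None
    return float(-np.log(a / b))


def coarse_grain(x, tau: int) -> np.ndarray:
    """Average non-overlapping windows of ``tau`` values (tail dropped)."""
    x = _as_series(x)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if x.size < tau:
        raise ValueError("series shorter than the coarse-graining scale")
    k = x.size // tau
    return x[:k * tau].reshape(k, tau).mean(axis=1)


def mse(x, scales=(1, 2, 3, 4), params: EntropyParams | None = None,
        n_required: int | None = MSE_REQUIRED_STRIDES) -> MseResult:
    """Multiscale entropy: SaEn of each coarse-grained series.

    The tolerance r is fixed from the original (scale-1) series SD and
    reused at every scale.  By default the input must be exactly 800
    strides (the first 800 of the longest bout); pass ``n_required=None``
    to lift that constraint for exploratory use.
    """
    x = _as_series(x)
    if n_required is not None and x.size != n_required:
        raise ValueError(f"multiscale entropy expects exactly {n_required} "
                         f"strides, got {x.size}")
    if params is None:
        params = EntropyParams.from_series(x)
    values, lengths = {}, {}
    for tau in scales:
        cg = coarse_grain(x, tau)
        lengths[tau] = cg.size
        values[tau] = saen(cg, params)
    return MseResult(scales=tuple(scales), values=values, lengths=lengths,
                     params=params)


def complexity_index(mse_values) -> float:
    """Trapezoidal area under the SaEn-versus-scale curve.

    ``mse_values`` is the SaEn sequence in scale order (unit scale
    spacing); any undefined (None/NaN) value makes the index undefined.
    """
    if isinstance(mse_values, MseResult):
        vals = [mse_values.values[tau] for tau in mse_values.scales]
    elif isinstance(mse_values, dict):
        vals = [mse_values[tau] for tau in sorted(mse_values)]
    else:
        vals = list(mse_values)
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("complexity index undefined: null SaEn at some scale")
    return float(np.trapezoid(np.asarray(vals, dtype=float)))
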