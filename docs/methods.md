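# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gaitcx`, in the order the pipeline applies them.

## Signal model and preprocessing

A recording is an irregularly timestamped tri-axial acceleration stream;
only the vertical axis is analysed (no rotation to a global frame — for
stride *timing*, orientation only matters up to a sign).  The vertical
axis is linearly interpolated onto a uniform 100 Hz grid from the first
to the last timestamp; duplicate timestamps are collapsed to their mean
first.  Linear interpolation was chosen over cubic to avoid ringing at
bout edges; its O(h²) error is negligible at 100 Hz relative to the
waveform's bandwidth.

The gravity bias is estimated as the whole-recording mean of the vertical
signal rather than a fixed 9.81 m/s², which makes the correction robust
to sensor calibration offset.  A phone carried upside-down in a front
pocket measures the negated vertical acceleration, so the demeaned signal
is multiplied by −1 when `invert` is set (the default).

Two streams are kept: the raw stream feeds the nonlinear measures, and a
low-pass filtered stream (4th-order Butterworth, 16 Hz cutoff) feeds the
linear measures and the event detector.  The filter is a **causal single
pass**, not forward–backward zero-phase: the downstream relocation step
explicitly compensates a small filter delay with a 3-frame offset, which
would be pointless after zero-phase filtering.  The group delay of this
filter at gait frequencies is ≈ 2–3 samples, which is exactly the scale
of that offset.

## Heel-contact detection

The detector approximates right-heel contacts in six steps on the
filtered stream:

1. causal 4th-order Butterworth high-pass at 0.1 Hz (drift removal);
2. cumulative trapezoidal integration to a vertical velocity;
3. differentiation by convolution with a first-derivative-of-Gaussian
   wavelet, standard deviation 12 samples at 100 Hz (scaled
   proportionally at other rates).  The discrete kernel's first moment is
   normalized so linear signals are differentiated exactly.  The sign
   convention makes the trace a smoothed acceleration, so trace minima
   align with acceleration minima near heel contact;
4. local minima of the trace are kept as candidates when separated by
   more than 0.8 s (the lower limit of a healthy adult's stride time;
   conflicts resolved greedily by depth) and more negative than 0.4 ×
   the median of the ten most-negative minima.  The threshold is relative,
   so detection is invariant to positive rescaling of the signal;
5. each candidate is chained forward to the next local maximum of the
   trace;
6. from that maximum, the first local minimum of the filtered
   acceleration is the heel contact.  Candidates that run off the end of
   the signal are dropped with a warning; duplicates collapse to one
   event.

Events are then relocated in the raw stream by starting three frames
before each filtered event and searching forward for the first raw local
minimum.  Local extrema are defined as strictly below/above both
neighbours, with plateaus reporting their first sample.  "Ten minimum CWT
values" is read as the ten most-negative local minima of the whole trace;
a first-10 or rolling-window reading would make the threshold depend on
recording order, which the relative-threshold intent contradicts.

## Bout segmentation

Bouts split at inter-contact gaps > 1.8 s.  A bout must have strictly
more than 24 strides (= inter-contact intervals); the first and last two
strides are then trimmed to exclude gait initiation/termination, and only
bouts retaining ≥ 20 strides are analysed — the accepted minimum for a
reliable stride-time variability estimate.  Stride count is defined as
the number of ISI values (events − 1).

## Measures

* **Linear** (≥ 20 strides): mean, sample SD (n−1 denominator throughout
  the package) and COV = 100·SD/mean.
* **DFA/FSI** (> 255 strides): mean-centre, cumulative-sum to a profile;
  for every integer box size n = 10…40 cut the profile into ⌊N/n⌋ boxes
  from the start (tail discarded — the single-forward-pass variant),
  least-squares detrend per box, per-box RMS of residuals, averaged
  across boxes; α is the OLS slope of log₁₀(mean RMS) on log₁₀(n).
* **ApEn** (Pincus, self-matches included) and **SaEn**
  (Richman–Moorman, self-matches excluded) with Chebyshev distance,
  m = 2, r = 0.15 × SD of the series.  SaEn uses the same N−m template
  starts at both lengths, which makes it exactly 0 on strictly periodic
  series; undefined cases (no matches) are returned as nulls with a
  warning, never silently zero.  The > 255-stride rule is a bout
  *eligibility* rule, enforced by the pipeline; the functions themselves
  accept any series (the test oracles run them at N ≤ 50).
* **MSE/CI** (exactly 800 strides — the first 800 of the longest bout):
  SaEn of coarse-grained series at scales 1–4 (non-overlapping means,
  tail dropped; lengths 800/400/266/200) with r held fixed from the
  scale-1 series, the usual multiscale convention; CI is the trapezoidal
  area under the SaEn-versus-scale curve.
* **SPD/EnHL** (same 800 strides): the series is reshaped for every
  stride-order separation s = 1…100 by the deal-into-s-piles permutation
  (offset o, o+s, o+2s, … for o = 0…s−1; s = 1 is the identity), and 100
  uniform random permutations provide surrogates.  SPD is the smallest s
  whose reshaped-series DFA α is strictly below the critical limit
  mean(α_rand) + 2·SD(α_rand); equality is not a crossing.  EnHL
  normalizes reshaped SaEn as (SaEn_reshape − SaEn_orig)/(SaEn_rand −
  SaEn_orig), a curve that is exactly 0 at s = 1 and approaches 1 under
  full randomization.  Because a half-life threshold of 0.5 is therefore
  crossed *from below*, EnHL is defined here as the first s at which the
  curve drops back below 0.5 after having exceeded it; if it never
  exceeds 0.5, EnHL is censored at 100.  Censoring (both measures) is
  reported explicitly.  Reshaped-series DFA uses the same box range
  10–40.

Participant aggregation: linear measures and FSI/ApEn/SaEn are computed
per qualifying bout and averaged within the participant; the participant
COV is recomputed as 100·SD/x̄ISI from the averaged SD and mean so the
COV identity holds on every emitted measure set.  Batch processing is
sequential and deterministic: per-participant surrogate seeds derive from
the global seed plus the participant index.

## Synthetic data

`generate_isi` draws stride-time series from four models: i.i.d.
Gaussian; exact fractional Gaussian noise via circulant embedding
(Davies–Harte — the target autocovariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H}
+ |k−1|^{2H}) is embedded in a circulant matrix whose FFT eigenvalues are
provably non-negative for fGn, so the construction is exact and the
long-range structure feeding the DFA tests is unbiased); a deterministic
periodic pattern; and a per-element Bernoulli mixture of the two.
Defaults (mean 1.12 s, SD 0.04 s, Hurst 0.9) represent healthy adult
free-living walking.  Values are clipped at a 0.4 s floor — half the
0.8 s detector separation limit, so clipping can never produce a
rule-violating series — and parameters for which more than 1 % of draws
would clip are rejected.  Each stochastic operation draws from its own
named sub-stream of the single integer seed.

`generate_recording` renders ISI series as a vertical acceleration
waveform: per stride a broad mid-stance dip (−4 m/s², sin² window on
stride phase 0.45–0.9), and per contact a sharp spike (+10 m/s², cos²
half-width 0.05 s, centred 65 ms before the contact) directly adjoining
a sharp trough (−8 m/s², cos² half-width 0.06 s) centred exactly on the
contact.  All components have zero slope at the contact time, so every
true contact is an exact local minimum of the analytic waveform.  The
geometry is chosen for the *detectability contract*, not biomechanical
realism: after the detector's ~0.12 s wavelet smoothing the mid-stance
dips are by far the deepest trace minima (one candidate per stride), the
smoothed spike-minus-trough residual peaks just before the contact
(providing the trace maximum the chain needs), and the acceleration
descends steeply from spike to trough with no flat region in which
sensor noise could fake an early local minimum.  Each bout gets one
lead-in mid-stance dip so its first contact is detectable by the same
chain.  Gravity offset, optional inversion, Gaussian timestamp jitter
(default 1 ms) and white sensor noise (default 0.05 m/s²) complete the
recording; bout gaps must exceed 1.8 s or ground-truth bouts would merge.

What the generator does **not** emulate: turning, stairs, shuffling or
pathological gait; tri-axial orientation dynamics (only a static
inversion); any empirically measured spectral content of pocket-worn
walking — the waveform is parametric.  Passing tests therefore
demonstrate correctness of the algorithms against known ground truth,
not field performance on real recordings.

## Numerical choices and problem sizes

Tolerances: entropy implementations match exhaustive double-loop oracles
to 1e−12; DFA affine invariance to 1e−10.  Detection fidelity is assessed
at a ±30 ms matching tolerance.  The test suite and the acceptance script
use series of N = 800–1600 strides, 20-seed averages for stochastic
properties, recordings up to ~30 minutes, and 10 replicates of the
100-surrogate/100-reshaping SPD comparison — sizes at which every
stochastic check is stable while the whole suite runs in well under a
minute of compute.

## Known limitations

* Detection quantizes event times to the 100 Hz grid (±5 ms), which adds
  a small MA(1) noise to ISI series and nudges DFA α of near-1/f series
  slightly upward.
* SaEn/MSE at scales 3–4 rest on 266/200 points, where sample-entropy
  estimates are noisy; nulls can occur for very regular series.
* SPD and EnHL are first-crossing statistics of noisy curves and can be
  censored at 100; censored values are flagged, not clamped silently.
* The EnHL crossing convention (first drop below 0.5 after exceeding it)
  is one of several defensible readings of a threshold rule on a curve
  that starts at 0; it is fixed and documented here.
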