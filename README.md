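# gaitcx

Stride-time variability and complexity analysis for pocket-worn smartphone
accelerometry.

## What it is for

When a person walks with a smartphone in their front pant pocket, the
vertical accelerometer axis shows a characteristic pattern at every right
heel contact.  From a long free-living recording one can recover each
walking bout's sequence of **inter-stride intervals** (ISI — the time
between consecutive right-heel contacts) and then ask two kinds of
question about stride-time variability:

* *How large is it?* — mean stride time x̄ISI (s), stride-time SD (s),
  and coefficient of variation COV = 100·SD/x̄ISI (%).
* *How is it structured in time?* — detrended fluctuation analysis
  (DFA) giving the fractal scaling index **FSI** (α ≈ 0.5 for
  uncorrelated, α → 1 for strongly persistent fluctuations); approximate
  and sample entropy (**ApEn**, **SaEn**; m = 2, r = 0.15·SD); multiscale
  entropy (**MSE**, scales 1–4) and its area-under-curve complexity index
  (**CI**); and two decay measures built on progressive reshaping of the
  series — **SPD** (statistical persistence decay: the stride-order
  separation at which DFA α of the reshaped series falls below the
  random-permutation critical limit mean(α_rand) + 2·SD(α_rand)) and
  **EnHL** (entropic half-life: the separation at which normalized SaEn,
  (SaEn_reshape − SaEn_orig)/(SaEn_rand − SaEn_orig), passes 0.5).

The package is aimed at gait researchers who want these measures from
raw phone recordings, and at methodologists who want a fully testable
reference implementation: a synthetic-data module generates acceleration
recordings and stride-time series (including exact fractional Gaussian
noise with a chosen Hurst exponent) with known ground truth, so every
pipeline stage is verifiable without access to field recordings.

## Pipeline

1. **Preprocess** — linearly resample the irregular vertical-axis samples
   to 100 Hz, remove the gravity bias (whole-recording mean), flip the
   sign for an upside-down pocket orientation, and keep two streams: raw,
   and low-pass filtered (causal 4th-order Butterworth, 16 Hz).
2. **Detect heel contacts** — high-pass 0.1 Hz, integrate to velocity,
   differentiate with a Gaussian-derivative continuous wavelet transform
   (scale 12 samples), find deep well-separated trace minima (> 0.8 s
   apart, below 40 % of the median of the ten deepest), chain each
   forward to the next trace maximum and then to the first acceleration
   minimum — the right-heel contact.  Events are then relocated in the
   raw stream (3-frame offset, forward search).
3. **Segment bouts** — split at inter-contact gaps > 1.8 s, keep bouts
   with more than 24 strides, trim two strides at each end, retain bouts
   of ≥ 20 strides.
4. **Measure** — linear measures on every bout (filtered stream);
   FSI/ApEn/SaEn on bouts of > 255 strides (raw stream); MSE, CI, SPD and
   EnHL on the first 800 strides of the longest bout.

## Worked example

```python
from gaitcx import (PipelineConfig, process_recording, generate_isi,
                    generate_recording)

# a ~30-minute recording of fGn stride times with known structure
isi = generate_isi("fgn", 1600, mean_s=1.12, sd_s=0.04, hurst=0.9, seed=42)
rec = generate_recording([isi], seed=42)

ms, bouts, warnings = process_recording(rec.accel, PipelineConfig(),
                                        participant_id="demo", seed=7)
print(f"xISI {ms.xisi:.4f} s   COV {ms.cov:.2f} %   FSI {ms.fsi:.3f}")
print(f"SPD {ms.spd} strides   EnHL {ms.enhl} strides")
```

prints

```
xISI 1.1355 s   COV 3.18 %   FSI 0.948
SPD 25 strides   EnHL 5 strides
```

The recovered mean stride time matches the generating mean (1.1355 s) to
within 0.0001 s, the COV matches the generating value (3.15 %) within
0.03 percentage points, and the FSI (0.95) sits close to the generating
Hurst exponent 0.9 — the detector's small quantization noise raises it
slightly.  SPD of 25 strides says the reshaped series stays
distinguishable from random permutations up to a stride-order separation
of 25; EnHL of 5 says half the series' predictability is lost by
separation 5.  More examples live in `examples/`.

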