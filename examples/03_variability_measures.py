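"""Linear and nonlinear stride-time variability of one ISI series.

Compares two 800-stride series with the same mean and SD but different
temporal structure: persistent fractional Gaussian noise versus an
uncorrelated shuffle of the same values.  The linear measures agree; the
structure-sensitive ones do not.
"""

import numpy as np

from gaitcx import EntropyParams, apen, dfa, generate_isi, linear_measures, \
    mse, complexity_index, saen

x = generate_isi("fgn", n=800, mean_s=1.12, sd_s=0.04, hurst=0.9, seed=5).values
shuffled = np.random.default_rng(5).permutation(x)

for name, series in [("fGn H=0.9", x), ("shuffled  ", shuffled)]:
    xisi, sd, cov = linear_measures(series)
    params = EntropyParams.from_series(series)
    alpha = dfa(series).alpha
    res = mse(series, params=params)
    print(f"{name}: xISI {xisi:.3f} s  COV {cov:.2f} %  FSI {alpha:.2f}  "
          f"ApEn {apen(series, params):.2f}  SaEn {saen(series, params):.2f}  "
          f"CI {complexity_index(res):.2f}")
# FSI near 0.9 marks statistical persistence; shuffling the same values
# drives it to ~0.5 (uncorrelated) while mean, SD and COV are unchanged.
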