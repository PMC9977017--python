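"""Fill gaps in a wearable signal with stochastic surrogate imputation.

Gaps longer than a threshold are filled by copying a donor segment of the
same duration from the gap's neighbourhood (side chosen by coin toss,
offset by a folded-normal draw scaled with the gap length) plus a small
Gaussian noise term. Repeating with different seeds yields an ensemble
whose spread measures imputation uncertainty.
"""

import numpy as np

from physiomot import TimestampedSeries, detect_gaps, generate_surrogate_ensemble, surrogate_impute

rng = np.random.default_rng(0)
t = np.arange(4000.0)
v = np.sin(t / 120.0) + 0.3 * rng.standard_normal(4000)
keep = np.ones(4000, dtype=bool)
keep[900:1020] = False     # a 2-minute gap
keep[2500:2560] = False    # a 1-minute gap
s = TimestampedSeries(t[keep], v[keep])

gaps = detect_gaps(s, th_g=10.0)
print("gaps >10 s before imputation:", [(g.t_b, g.t_e, g.g_l) for g in gaps])

imputed = surrogate_impute(s, th_g=10.0, seed=7)
print("gaps >10 s after imputation: ", detect_gaps(imputed, th_g=10.0))
print(f"samples: {len(s)} -> {len(imputed)}")

ens = generate_surrogate_ensemble(s, th_g=10.0, m=100, base_seed=0)
filled = [m.v[np.searchsorted(m.t, np.setdiff1d(m.t, s.t))] for m in ens.members]
means = [f.mean() for f in filled]
print(f"ensemble of {len(ens)} members; imputed-region mean "
      f"{np.mean(means):.3f} +- {np.std(means):.3f} (signal mean {v.mean():.3f})")
# The member-to-member spread of the imputed values is what propagates into
# the variance features of the multiscale blocks.
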