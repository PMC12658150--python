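"""Negative-binomial regression with position-interaction contrasts.

Builds the main-effect + sum-coded-position + interaction design, plants
a TSS-specific interaction for one feature, fits the count model with a
log-expected offset and tests the TSS-vs-far contrasts with single-step
max-|z| family-wise adjustment.
"""

import numpy as np
import pandas as pd

from tssmut import regression as rg

rng = np.random.default_rng(1)
n = 10_000
feat = pd.DataFrame({"dsb_density": rng.normal(size=n),
                     "gc_content": rng.normal(size=n)})
pos = pd.Series(rng.choice(["downstream_TSS", "downstream_far",
                            "upstream_TSS", "upstream_far"], size=n))

spec, X, idx = rg.build_design(feat, pos, interactions=True)
print(f"design: {X.shape[1]} columns = 1 + m + (K-1) + m(K-1) for m=2, K=4")

eta = 0.4 + 0.25 * feat["dsb_density"].to_numpy() * (pos == "downstream_TSS").to_numpy()
mu = np.exp(eta)
y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))

fit = rg.fit_count_model(X, y, np.zeros(n), family="negative_binomial")
stat, flag = rg.dispersion_diagnostic(fit)
print(f"NB dispersion alpha = {fit.alpha:.3f}; Pearson chi2/df = {stat:.2f} ({flag})")

C = rg.tss_effect_contrasts(spec)
res = rg.contrast_tests(fit, C, adjust="single_step_maxz", seed=0)
print("\nTSS-vs-far interaction contrasts (adjusted):")
for name, row in res.iterrows():
    if name.endswith("TSS-far"):
        print(f"  {name:35s} est {row.estimate:+.3f}  p_adj {row.p_adj:.2e}")
print("\nonly dsb_density x downstream_TSS carries the planted +0.25 "
      "effect; everything else stays consistent with zero.")
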