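"""Bias-corrected differential abundance with known ground truth.

Simulates a 200-sample, 150-feature benchmark whose counts follow the
log-linear absolute-abundance model with sample-specific sampling fractions,
fits the bias-corrected engine, and scores recovery of the designed
coefficients.
"""

import numpy as np

from gcgut import fit_dabc, significant_features, simulate_da_dataset

table, design, truth = simulate_da_dataset(seed=1)
fit = fit_dabc(table, design)

r = np.corrcoef(fit.log_sampling_fraction.values,
                truth.log_sampling_fraction.values)[0, 1]
print(f"sampling-fraction recovery (correlation): {r:.3f}")

cols = [c for c in design.columns if c != "Intercept"]
nn = truth.nonnull_features()
mask = (truth.beta.loc[nn, cols] != 0).values
err = (fit.beta.loc[nn, cols] - truth.beta.loc[nn, cols]).abs().values[mask]
print(f"non-null coefficient MAE: {err.mean():.3f} log-fold "
      f"(designed effects are 0.5-1.5)")

sig, pct = significant_features(fit, "EarlyPreGC:Age")
print(f"features with a significant early-gestation-by-age interaction "
      f"(BH q < 0.05): {len(sig)} of {len(fit.features)} ({pct}%)")
# 30 features carry designed early-gestation GC effects; the engine should
# flag essentially those and keep false positives near the nominal level.
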