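"""Where do clinicians under-grade?  Expected-score and difference curves.

Fits the GRM to attenuated-clinic synthetic data, then computes each
item's posterior expected-score traceline over latent severity theta, the
patient-average curve, and per-clinic difference curves whose across-clinic
mean is the headline summary: positive values mean clinics grade lower
than patients at that latent severity.
"""

import warnings

import numpy as np

from grmagree import (
    McmcConfig, SimConfig, ThetaGrid, difference_curves, fit_grm, generate,
    item_curves, patient_average_curve,
)

table, _ = generate(SimConfig(n_patients=300, n_clinics=5, seed=23))
mc = McmcConfig(n_adapt=400, n_burn=500, n_keep=1000, thin=1, n_chains=1, seed=2)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    draws = fit_grm(table, config=mc)

grid = ThetaGrid(-3, 3, 0.5)
cs = item_curves(draws, grid)
pat = patient_average_curve(cs)
diff = difference_curves(cs)

print(f"{'theta':>6} {'patient avg':>12} {'mean clinic':>12} {'difference':>11}")
clinic_mean = pat - diff.mean_difference
for g, p, c, d in zip(grid.values, pat, clinic_mean, diff.mean_difference):
    print(f"{g:>6.1f} {p:>12.2f} {c:>12.2f} {d:>11.2f}")

peak = grid.values[int(np.argmax(diff.mean_difference))]
print(f"\nmax mean difference {diff.mean_difference.max():.2f} grades at "
      f"theta = {peak:.1f}")
# Near-zero differences for theta <= 0 (mild symptoms) and a >1-grade gap
# at high theta reproduce the characteristic pattern: clinician
# underestimation grows with the severity of the underlying adverse event.
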