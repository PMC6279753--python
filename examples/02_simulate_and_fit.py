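"""Simulate a study-shaped dataset and recover its GRM parameters by MCMC.

Generates 300 patients in 5 clinic clusters with three pain attributes,
clinicians attenuated relative to patients (discrimination halved,
thresholds shifted up one unit), fits the Bayesian graded response model
with a shortened chain schedule, and prints the item-parameter summary
next to the generating truth.
"""

import warnings

from grmagree import McmcConfig, SimConfig, fit_grm, generate, summarize, diagnose

config = SimConfig(n_patients=300, n_clinics=5, seed=11)
table, truth = generate(config)
print(f"simulated {table.n_patients} patients, "
      f"{len(table.attribute_items())} attributes, "
      f"{len(table.clinic_items())} clinics; "
      f"{(table.responses == -2).sum()} skip-coded cells")

mc = McmcConfig(n_adapt=500, n_burn=1000, n_keep=800, thin=10, n_chains=2, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    draws = fit_grm(table, config=mc)

summary = summarize(draws)
truths = list(truth.patient_items) + list(truth.clinic_items)
print(f"\n{'item':<14}{'true alpha':>11}{'post mean':>11}{'95% interval':>22}")
for item, p in zip(draws.items, truths):
    row = summary.loc[f"alpha[{item.item_id}]"]
    interval = f"[{row['q2.5']:.2f}, {row['q97.5']:.2f}]"
    print(f"{item.item_id:<14}{p.alpha:>11.2f}{row['mean']:>11.2f}{interval:>22}")

diag = diagnose(draws)
print(f"\nmax split-Rhat: {diag.rhat.max():.3f}  "
      f"(params > {diag.threshold}: {diag.n_bad_rhat})")
# Clinic discriminations are recovered with wider intervals (~60
# observations each).  Very high patient discriminations (severity, 5.69)
# are shrunk downward: skip coding removes the severity/interference
# responses of exactly the asymptomatic patients, and the weakly
# informative prior pulls extreme slopes in.  An Rhat near 1 indicates the
# two chains agree; with thin=1 this dataset shows visible autocorrelation,
# hence the thinned schedule here.
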