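# grmagree

Bayesian graded-response-model (GRM) analysis of agreement between
multi-attribute patient-reported adverse-event (AE) ratings and
unidimensional clinician grades.

## The problem

In cancer trials the same symptomatic AE (pain, fatigue, nausea, ...) is
graded twice: by the clinician with a single CTCAE grade, and by the
patient with up to three PRO-CTCAE attributes — frequency, severity,
interference with daily activities — each on a 0–4 ordinal scale.
Traditional concordance statistics (Cohen's weighted κ, Spearman's *r*, raw
percent agreement) compress the comparison into one coefficient and cannot
say *where* along the severity continuum raters diverge. They are also
awkward when attributes are multiple, data are missing by design (survey
branching skips follow-up attributes when the first is 0), and clinician
identities are only available as site × cancer-type "clinic" clusters.

`grmagree` implements a raters-as-items alternative. Every rating source —
each patient attribute and each clinic cluster — is an *item* in a graded
response model over a single latent AE level θ:

    P(Y_ij ≥ k | θ_i) = logistic(α_j θ_i − κ_jk),     k = 1..K−1,

with discrimination α_j > 0, ordered thresholds κ_j1 < … < κ_j,K−1 (the
rater's internal decision criteria), and θ_i ~ N(0, 1). Estimation is by
MCMC (adaptive random-walk Metropolis-within-Gibbs) with weakly
informative priors α ~ N(1.0, 2.5²) truncated at 0 and κ ~ N(0.0, 2.5²);
missing responses — clinics that never saw a patient, skip-coded
attributes — contribute nothing to the likelihood. The posterior expected
item score

    E[Y_j | θ] = Σ_k P(Y_j ≥ k | θ)

is the model-based AE grade; the patient-average curve minus each clinic's
curve, averaged over clinics, localises clinician under-/over-estimation
as a function of latent severity. The classical metrics are included for
comparison, computed directly on contingency tables (with an exact
expanded-pairs equivalence).

## Worked example

```python
from grmagree import pain_severity_crosstab, concordance_metrics

res = concordance_metrics(pain_severity_crosstab(), scheme="linear")
print(res.n, res.diagonal_count, round(res.percent_agreement, 4),
      round(res.weighted_kappa, 4), round(res.spearman_r, 4))
# 525 132 0.2514 0.1473 0.4361
```

Of 525 patients with both pain ratings, only 132 pairs sit on the main
diagonal (raw agreement 0.25); linear weighted κ = 0.15 and Spearman
*r* = 0.44 indicate low-to-moderate overall concordance — but nothing
about where it fails. The model-based view:

```python
import warnings
from grmagree import (SimConfig, McmcConfig, generate, fit_grm,
                      item_curves, difference_curves, ThetaGrid)

table, truth = generate(SimConfig(n_patients=300, n_clinics=5, seed=23))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    draws = fit_grm(table, config=McmcConfig(n_adapt=400, n_burn=500,
                                             n_keep=1000, thin=1,
                                             n_chains=1, seed=2))
diff = difference_curves(item_curves(draws, ThetaGrid(-3, 3, 0.5)))
for g, d in zip(diff.grid.values, diff.mean_difference):
    print(f"theta {g:+.1f}: mean difference {d:+.2f}")
```

prints a mean patient-minus-clinic difference near 0 for θ ≤ 0 that rises
to about +1.4 grades at θ ≈ 1.5: with clinics attenuated (discrimination
halved, thresholds shifted up one unit — the generator's default),
clinician underestimation is concentrated in moderate-to-severe latent AE
levels and absent for mild ones. The scripts in `examples/` walk through
each capability (concordance metrics, simulate-and-fit recovery,
difference curves, hypothetical-patient θ placement); a thin CLI
(`grmagree simulate|fit|curves|concord`) wraps the same functions for
shell pipelines.

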