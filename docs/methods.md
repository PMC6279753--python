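# Methods

## Model

One adverse event (AE) is analysed at a time. Each rating source is an
item in Samejima's graded response model: patient-reported attributes
(frequency, severity, interference; 0–4) and clinic clusters (one
clinician CTCAE grade per patient, attributed to the patient's site ×
cancer-type stratum because clinician identities are unavailable). For
item *j* with K ordered categories and latent AE level θ_i,

P(Y_ij ≥ k | θ_i) = logistic(α_j θ_i − κ_jk), k = 1..K−1,

in slope–intercept form: α_j is the discrimination, κ_j the ordered
threshold intercepts ("decision criteria"). The slope–intercept
parameterisation (rather than the difficulty form α(θ − b)) was chosen
because published estimates of this kind report intercept-scale
thresholds (e.g. κ ≈ 9 with α ≈ 5.7), and because the cut labels
("1–4 vs. 0", …, "4 vs. 0–3") refer to cumulative splits. The link is
logistic; a probit link would change nothing qualitative.

Assumptions: a single latent θ drives all of a patient's attribute
responses and their clinician's grade (local independence given θ);
θ ~ N(0, 1), which fixes the location and scale of the latent metric so
curves are read in population-SD units; raters share the same category
semantics (cut k means the same split for every item).

Missingness — clinic items never rated for a patient (N/A padding) and
skip-coded attributes — enters the likelihood as absent data: the
posterior is updated from available responses only. Both missing states
are nevertheless kept distinct in the data model (`NOT_RATED` vs
`SKIPPED`) for reporting and round-tripping. Skip-coded missingness is
*not* ignorable in the usual MAR sense (skipping is determined by the
first attribute's value); treating it as uninformative follows the
analysis convention for branched instruments and is a known limitation,
not a claim of MAR validity.

## Priors and identification

α_j ~ N(1.0, 2.5²) truncated to α > 0; κ_jk ~ N(0.0, 2.5²) restricted to
the ordered region; θ_i ~ N(0, 1) fixed. The prior location of 1.0 on the
discriminations encodes "an average slope of 1"; both prior moments are
configurable (`PriorSpec`). Truncation at zero removes the sign-flip
(label-switching) mode; threshold ordering is enforced through the
support restriction rather than a gap reparameterisation — random-walk
proposals that violate ordering are simply rejected, which targets the
same truncated prior without Jacobian bookkeeping. Categories never
observed in the data keep their thresholds (informed by the prior), so
threshold indexing stays aligned with the K declared categories.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs:

* a vectorised sweep over all patient θ_i (conditionally independent
  blocks given item parameters — simultaneous independent accept/reject
  is a valid Gibbs sweep);
* one joint proposal per item over (α_j, κ_j).

Per-block Gaussian step sizes are tuned toward 0.44 acceptance by a
Robbins–Monro recursion during the adaptation phase only, then frozen;
the post-adaptation chain is a fixed-kernel Markov chain. The schedule
(adaptation / burn-in / retained × thinning) is honoured exactly and a
fixed seed reproduces draws bit for bit (per-chain generators seeded as
`[seed, chain]`). Defaults mirror the long-schedule convention (1000
adaptation, 5000 burn-in, 8000 retained after thinning by 10); two chains
by default so split-R̂ is available. Initialisation is deterministic and
data-informed: α = 1, κ matched to the item's observed cumulative
proportions at θ = 0 (clipped, forced strictly increasing), θ = 0.

Items with zero observations are dropped with a warning; items observed
in a single category are retained but flagged (their posteriors are
prior-dominated). Convergence diagnostics (split-R̂, bulk ESS) are
computed with arviz; they are generic chain diagnostics, not a model-fit
assessment — infit/outfit-style fit analysis is out of scope because the
self-rating design does not carry enough information for it.

For strongly discriminating items (α ≈ 5) random-walk chains are
noticeably autocorrelated at thin = 1; the examples use thinned longer
schedules when a clean R̂ matters. Very large generating α are also
shrunk toward the prior when skip coding removes the very responses
(severity/interference of asymptomatic patients) that would pin the
slope; this is information loss in the design, not a sampler defect.

## Curves

Expected item scores E[Y | θ] = Σ_k P(Y ≥ k | θ) are evaluated on a θ
grid (default [−3, 3] step 0.05) draw by draw and then averaged —
the posterior mean of the model-fitted response, not the response at the
posterior-mean parameters; bands are empirical 2.5/97.5% quantiles. The
patient summary is the unweighted mean over attribute-item curves
(whether the original analysis weighted by attribute or patient counts is
unstated; unweighted is documented and simplest). Difference curves are
patient-average minus per-clinic curve, so positive = clinic
underestimation; their unweighted across-clinic mean is the headline
curve. All clinics are kept regardless of patient count (sparse clinics
just have wide bands); a minimum-observation filter is available in
`fit_grm`'s dropping rule only for empty items.

Hypothetical patients are placed on the θ axis by quadrature: with item
parameters fixed at posterior means, the single-patient posterior
N(0,1)·Π P(y | θ) is integrated on a fine grid (default step 0.001 over
±6), returning the posterior mean θ.

## Synthetic data

The generator emulates the target study design: default 940 patients in
45 clinics (uniform assignment; a proportions option skews it), three
attributes with K = 5, θ ~ N(0,1), all responses drawn from the GRM at
the patient's θ, the clinician grade drawn from the patient's own clinic
item at the same θ (no rater-specific latent shift), skip coding applied
when the first attribute is 0. Default patient-item truths use
published-magnitude pain parameters (α 4.3–5.7, κ −6.5..+9.1) —
illustrative, not estimated. The clinician side defaults to an
attenuation rule relative to the mean patient profile: α × 0.5, κ + 1,
with N(0, 0.2²) jitter per clinic, reproducing the qualitative pattern
that clinics discriminate less sharply and hold higher thresholds.
Clinic indices are relabelled to first-appearance order in the patient
sequence so simulated files survive write→read round trips (the reader
assigns clinic indices by first appearance, the only deterministic order
available).

What the generator does not emulate: demographic covariates,
missing-not-at-random mechanisms beyond the skip rule, within-clinic
clinician heterogeneity, multi-AE correlation. Passing recovery tests on
this generator therefore show correctness of the machinery under the
stated model, not robustness to real-data violations of it.

## Validation suites and problem sizes

Two seeded replicate suites (`grmagree.validation`) exercise the full
generate → fit → summarise pipeline with a shortened schedule (400
adaptation, 500 burn-in, 1000 retained, thin 1, one chain), sized so each
replicate fits in a few seconds:

* **Recovery**: 20 replicates, n = 400 patients, 3 patient + 5 clinic
  items, truths drawn with α ∈ [1, 3], first threshold ∈ [−3, −1], gaps
  ∈ [0.5, 1.5]; pooled 95% credible-interval coverage of all α and κ is
  required ≥ 80% (Monte-Carlo and short-chain slack below the nominal
  95%; measured ≈ 85–90%).
* **Attenuation**: 20 replicates, n = 300, 5 clinics, α × 0.5 / κ + 1
  clinics; the fitted across-clinic mean difference must stay within ±1
  grade for θ ≤ 0 and exceed +1 grade somewhere in θ ∈ [1, 3] — the
  assertable form of "underestimation is pronounced for moderate/severe
  AEs and mild for mild ones".

## Concordance metrics

Weighted κ is computed from the contingency table (zero-padded to square
over the union of labels): κ_w = 1 − Σ w O / Σ w E with w = |i−j|
(linear) or (i−j)² (quadratic). Linear weighting is the default because
it is the scheme that reproduces the published pain-table value (0.15;
quadratic gives 0.29); results always carry the scheme tag. Spearman's
*r* uses midranks computed in closed form from the margins, algebraically
identical to expanding the table to n pairs and rank-correlating.
Diagonal statistics on rectangular tables (5 patient categories × 4
observed clinician grades) match categories by label. Degenerate inputs
(empty table, single-category margins) raise `DegenerateTableError`
rather than returning NaN. p-values and confidence intervals for these
metrics are deliberately out of scope.

## Numerical notes

Category probabilities are adjacent differences of logistic terms;
log-likelihood floors probabilities at 1e−300 before logging (relevant
only in saturated tails). Posterior summaries use empirical quantiles
(linear interpolation). The truncated-normal prior constant is included
in `log_posterior` so densities are proper, though MH only needs ratios.
Seeds are NumPy `SeedSequence`-derived throughout; every public
stochastic entry point takes an explicit seed.
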