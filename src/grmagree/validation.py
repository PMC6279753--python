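"""Simulation-based checks of the full pipeline under known truth.

Two seeded replicate suites exercise generate -> fit -> summarise end to
end:

* :func:`run_recovery_suite` -- draws item truths at random (moderate
  discriminations, well-spaced thresholds), fits the model with a shortened
  chain schedule, and reports how often the 95% credible intervals cover
  the true discriminations and thresholds;
* :func:`run_attenuation_suite` -- generates data with attenuated clinics
  (discrimination halved, thresholds shifted up one unit relative to the
  patient average) and checks the fitted across-clinic mean difference
  curve for the expected signature: near zero for mild latent severity,
  exceeding one grade somewhere in the moderate/severe range.

Problem sizes default to a few hundred patients and a handful of clinics so
one replicate fits in seconds; the qualitative conclusions do not depend on
the exact sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grm import ItemParams
from .inference import McmcConfig, fit_grm, summarize
from .curves import ThetaGrid, item_curves, difference_curves
from .simulate import SimConfig, generate

#: shortened chain schedule used by the replicate suites
SHORT_SCHEDULE = dict(n_adapt=400, n_burn=500, n_keep=1000, thin=1, n_chains=1)


def random_item_params(
    rng: np.random.Generator,
    n_categories: int = 5,
    alpha_range: tuple[float, float] = (1.0, 3.0),
    gap_range: tuple[float, float] = (0.5, 1.5),
    kappa1_range: tuple[float, float] = (-3.0, -1.0),
) -> ItemParams:
    """A random, identifiable item truth: moderate discrimination and
    thresholds spread so every category has appreciable mass under
    theta ~ N(0,1)."""
    alpha = rng.uniform(*alpha_range)
    k1 = rng.uniform(*kappa1_range)
    gaps = rng.uniform(*gap_range, size=n_categories - 2)
    kappa = k1 + np.concatenate(([0.0], np.cumsum(gaps)))
    return ItemParams(float(alpha), tuple(kappa))


@dataclass
class RecoveryResult:
    """Credible-interval coverage of the generating truth, pooled over
    replicates."""

    n_replicates: int
    n_alpha: int
    n_kappa: int
    alpha_covered: int
    kappa_covered: int

    @property
    def coverage(self) -> float:
        return (self.alpha_covered + self.kappa_covered) / (self.n_alpha + self.n_kappa)

    @property
    def alpha_coverage(self) -> float:
        return self.alpha_covered / self.n_alpha

    @property
    def kappa_coverage(self) -> float:
        return self.kappa_covered / self.n_kappa


def recovery_replicate(
    seed: int,
    n_patients: int = 400,
    n_attributes: int = 3,
    n_clinics: int = 5,
    schedule: dict | None = None,
) -> tuple[int, int, int, int]:
    """One simulate-then-fit replicate.

    Returns (alpha instances covered, total alpha instances, kappa
    instances covered, total kappa instances) for the 95% credible
    intervals against the generating truth.
    """
    rng = np.random.default_rng(seed)
    patient_items = tuple(random_item_params(rng) for _ in range(n_attributes))
    clinic_items = tuple(random_item_params(rng) for _ in range(n_clinics))
    config = SimConfig(
        n_patients=n_patients, n_clinics=n_clinics, n_attributes=n_attributes,
        patient_items=patient_items, clinic_items=clinic_items,
        skip_rule=True, seed=seed,
    )
    table, truth = generate(config)
    mc = McmcConfig(**(schedule or SHORT_SCHEDULE), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_grm(table, config=mc)
    summary = summarize(draws)

    truths = {it.item_id: p for it, p in zip(
        table.items, list(truth.patient_items) + list(truth.clinic_items))}
    a_cov = a_tot = k_cov = k_tot = 0
    for item in draws.items:
        true = truths[item.item_id]
        row = summary.loc[f"alpha[{item.item_id}]"]
        a_tot += 1
        a_cov += int(row["q2.5"] <= true.alpha <= row["q97.5"])
        for k in range(1, item.n_categories):
            row = summary.loc[f"kappa[{item.item_id},{k}]"]
            k_tot += 1
            k_cov += int(row["q2.5"] <= true.kappa[k - 1] <= row["q97.5"])
    return a_cov, a_tot, k_cov, k_tot


def run_recovery_suite(
    n_replicates: int = 20, seed: int = 0, **kwargs
) -> RecoveryResult:
    """Pooled credible-interval coverage over seeded replicates."""
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    a_cov = a_tot = k_cov = k_tot = 0
    for rep_seed in base:
        ac, at, kc, kt = recovery_replicate(int(rep_seed), **kwargs)
        a_cov += ac; a_tot += at; k_cov += kc; k_tot += kt
    return RecoveryResult(n_replicates, a_tot, k_tot, a_cov, k_cov)


@dataclass
class AttenuationResult:
    """Signature of clinician underestimation in fitted difference curves."""

    n_replicates: int
    n_with_signature: int
    max_mean_difference: list[float]

    @property
    def fraction(self) -> float:
        return self.n_with_signature / self.n_replicates


def attenuation_replicate(
    seed: int,
    n_patients: int = 300,
    n_clinics: int = 5,
    alpha_multiplier: float = 0.5,
    kappa_shift: float = 1.0,
    schedule: dict | None = None,
    grid: ThetaGrid = ThetaGrid(-3.0, 3.0, 0.1),
) -> tuple[bool, float]:
    """Fit one attenuated-clinic dataset and test the difference-curve
    signature: |mean difference| <= 1 for theta <= 0, and mean difference
    > +1 somewhere in theta in [1, 3].

    Returns (signature holds, maximum of the mean difference curve).
    """
    config = SimConfig(
        n_patients=n_patients, n_clinics=n_clinics,
        alpha_multiplier=alpha_multiplier, kappa_shift=kappa_shift,
        seed=seed,
    )
    table, _ = generate(config)
    mc = McmcConfig(**(schedule or SHORT_SCHEDULE), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_grm(table, config=mc)
    cs = item_curves(draws, grid)
    diff = difference_curves(cs)
    g = grid.values
    md = diff.mean_difference
    mild_ok = bool(np.all(np.abs(md[g <= 0]) <= 1.0))
    severe_ok = bool(np.any(md[(g >= 1) & (g <= 3)] > 1.0))
    return mild_ok and severe_ok, float(md.max())


def run_attenuation_suite(
    n_replicates: int = 20, seed: int = 0, **kwargs
) -> AttenuationResult:
    """Count replicates showing the clinician-underestimation signature."""
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    hits = 0
    maxima = []
    for rep_seed in base:
        ok, mx = attenuation_replicate(int(rep_seed), **kwargs)
        hits += int(ok)
        maxima.append(mx)
    return AttenuationResult(n_replicates, hits, maxima)
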