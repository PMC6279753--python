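"""Synthetic PRO-CTCAE/CTCAE-like data with known GRM truth.

The generator emulates the structure of a multicentre AE-grading study:
patients nested in site x cancer-type clinic clusters, two or three
patient-reported attributes per AE on 0..K-1 scales, a single clinician
grade per patient supplied by the patient's own clinic, survey-branching
skip missingness (first attribute 0 silences the rest), and a clinician
side that can be attenuated relative to patients (lower discrimination,
higher thresholds) to mimic the empirically observed pattern that
clinicians under-grade relative to patients.

Every response -- patient attributes and the clinician grade alike -- is
drawn from the graded response model at the patient's own latent severity
theta_i ~ N(0, 1); the clinician shares the patient's theta (all items load
on one latent variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ClinicKey, RatingsTable, restructure_to_items, apply_skip_coding,
)
from .grm import ItemParams, category_probs

#: Illustrative default truth for a three-attribute AE, chosen so synthetic
#: tracelines resemble published pain estimates in magnitude (alpha ~ 4-6,
#: kappa spanning roughly -6..+9).  Illustrative, not estimated.
DEFAULT_PATIENT_PARAMS: tuple[ItemParams, ...] = (
    ItemParams(5.04, (-2.58, 0.41, 3.99, 6.98)),   # frequency-like
    ItemParams(5.69, (-6.46, 1.21, 5.48, 9.10)),   # severity-like
    ItemParams(4.33, (-0.92, 1.78, 4.25, 6.70)),   # interference-like
)

_ATTRIBUTE_NAMES = ("frequency", "severity", "interference")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped generating conditions.

    Defaults emulate the target design: 940 patients in 45 clinic clusters,
    three attributes on 5-point scales, skip coding on, and clinics
    attenuated (alpha halved, thresholds shifted up one unit) relative to
    the average patient-attribute profile, with a little clinic-to-clinic
    jitter.
    """

    n_patients: int = 940
    n_clinics: int = 45
    n_attributes: int = 3
    n_categories: int = 5
    patient_items: tuple[ItemParams, ...] | None = None
    clinic_items: tuple[ItemParams, ...] | None = None
    alpha_multiplier: float = 0.5
    kappa_shift: float = 1.0
    clinic_jitter_sd: float = 0.2
    skip_rule: bool = True
    clinic_probs: tuple[float, ...] | None = None
    ae_name: str = "pain"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clinics > self.n_patients:
            raise ValueError("n_clinics cannot exceed n_patients")
        if self.n_attributes not in (2, 3):
            raise ValueError("n_attributes must be 2 or 3")
        if self.alpha_multiplier <= 0:
            raise ValueError("alpha_multiplier must be > 0")

    def resolved_patient_items(self) -> tuple[ItemParams, ...]:
        if self.patient_items is not None:
            if len(self.patient_items) != self.n_attributes:
                raise ValueError(
                    f"{len(self.patient_items)} patient item params for "
                    f"{self.n_attributes} attributes")
            return tuple(self.patient_items)
        if self.n_categories != 5:
            raise ValueError(
                "default patient truth is defined for 5 categories; supply "
                "patient_items for other K")
        # two-attribute AEs keep the severity- and interference-like items
        return DEFAULT_PATIENT_PARAMS[-self.n_attributes:]


@dataclass
class SimTruth:
    """Generating ground truth: item parameters, thetas, clinic assignment."""

    patient_items: list[ItemParams]
    clinic_items: list[ItemParams]
    thetas: np.ndarray
    clinic_of: np.ndarray  # 1-based clinic index per patient
    attribute_names: list[str] = field(default_factory=list)


def make_attenuated_clinics(
    reference: ItemParams,
    alpha_multiplier: float,
    kappa_shift: float,
    n_clinics: int,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[ItemParams]:
    """Clinic item truths derived from a reference patient profile.

    Each clinic gets ``alpha = reference.alpha * alpha_multiplier`` and
    ``kappa = reference.kappa + kappa_shift``, plus independent normal
    jitter of sd ``jitter_sd`` on every parameter.  Jittered thresholds are
    re-sorted (with a minimal gap) so ordering always holds; alpha is kept
    strictly positive.
    """
    if alpha_multiplier <= 0:
        raise ValueError("alpha_multiplier must be > 0")
    rng = np.random.default_rng(rng)
    base_alpha = reference.alpha * alpha_multiplier
    base_kappa = np.asarray(reference.kappa) + kappa_shift
    out = []
    for _ in range(n_clinics):
        a = base_alpha + jitter_sd * rng.standard_normal()
        a = max(a, 0.05)
        k = np.sort(base_kappa + jitter_sd * rng.standard_normal(base_kappa.size))
        for i in range(1, k.size):  # strict ordering after sorting ties
            k[i] = max(k[i], k[i - 1] + 1e-6)
        out.append(ItemParams(float(a), tuple(k)))
    return out


def _mean_profile(items: tuple[ItemParams, ...]) -> ItemParams:
    alpha = float(np.mean([it.alpha for it in items]))
    kappa = np.mean([it.kappa for it in items], axis=0)
    return ItemParams(alpha, tuple(kappa))


def _clinic_site_disease(n_clinics: int) -> list[tuple[str, str]]:
    """Deterministic site x disease-group labels forming n distinct pairs."""
    diseases = ["breast", "lung", "gastrointestinal", "genitourinary",
                "hematological"]
    out = []
    for c in range(n_clinics):
        site = f"site{c // len(diseases) + 1:02d}"
        out.append((site, diseases[c % len(diseases)]))
    return out


def generate(config: SimConfig = SimConfig()) -> tuple[RatingsTable, SimTruth]:
    """Draw a complete synthetic ratings table plus its generating truth.

    theta_i ~ N(0,1); every attribute response and the patient's single
    clinician grade are drawn from the GRM category probabilities at
    theta_i; the clinician grade lands in the patient's own clinic item and
    all other clinic items are NOT_RATED; the skip rule (first attribute 0
    silences later attributes) is applied last when enabled.  A fixed seed
    reproduces the table exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_items = config.resolved_patient_items()
    attr_names = list(_ATTRIBUTE_NAMES[-config.n_attributes:]) \
        if config.n_attributes == 2 else list(_ATTRIBUTE_NAMES)

    if config.clinic_items is not None:
        if len(config.clinic_items) != config.n_clinics:
            raise ValueError(
                f"{len(config.clinic_items)} clinic item params for "
                f"{config.n_clinics} clinics")
        clinic_items = list(config.clinic_items)
    else:
        clinic_items = make_attenuated_clinics(
            _mean_profile(patient_items), config.alpha_multiplier,
            config.kappa_shift, config.n_clinics, config.clinic_jitter_sd,
            rng,
        )

    thetas = rng.standard_normal(n)

    if config.clinic_probs is None:
        clinic_of = rng.integers(1, config.n_clinics + 1, size=n)
    else:
        probs = np.asarray(config.clinic_probs, dtype=float)
        if probs.size != config.n_clinics:
            raise ValueError("clinic_probs length must equal n_clinics")
        probs = probs / probs.sum()
        clinic_of = rng.choice(np.arange(1, config.n_clinics + 1), size=n, p=probs)

    # relabel clinics to first-appearance order in the patient sequence so
    # the numbering is canonical and survives a write/read round trip;
    # clinic_items is permuted alongside to keep the truth aligned
    remap: dict[int, int] = {}
    for c in clinic_of:
        if int(c) not in remap:
            remap[int(c)] = len(remap) + 1
    for c in range(1, config.n_clinics + 1):
        remap.setdefault(c, len(remap) + 1)
    clinic_of = np.array([remap[int(c)] for c in clinic_of])
    reordered = [None] * config.n_clinics
    for old, new in remap.items():
        reordered[new - 1] = clinic_items[old - 1]
    clinic_items = reordered

    def draw(params: ItemParams, th: np.ndarray) -> np.ndarray:
        probs = category_probs(params, th)
        u = rng.random(th.shape)
        return (probs.cumsum(axis=-1) < u[..., None]).sum(axis=-1)

    patients = [f"{i + 1:04d}" for i in range(n)]
    patient_block = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    for name, params in zip(attr_names, patient_items):
        patient_block[name] = draw(params, thetas)

    grades = np.empty(n, dtype=int)
    for c in range(1, config.n_clinics + 1):
        mask = clinic_of == c
        if mask.any():
            grades[mask] = draw(clinic_items[c - 1], thetas[mask])
    clinician_block = pd.Series(grades, index=patients, dtype=float)

    # clinic_index must match the truth's clinic numbering even if some
    # clinic happens to receive no patients, so keys are built directly
    # rather than through first-appearance assignment
    pairs = _clinic_site_disease(config.n_clinics)
    keys = {
        patients[i]: ClinicKey(*pairs[clinic_of[i] - 1], int(clinic_of[i]))
        for i in range(n)
    }

    table = restructure_to_items(
        patient_block, clinician_block, keys, ae_name=config.ae_name,
        n_categories=config.n_categories,
    )
    if config.skip_rule:
        table = apply_skip_coding(table, attr_names)
    table.validate()

    truth = SimTruth(
        patient_items=list(patient_items),
        clinic_items=clinic_items,
        thetas=thetas,
        clinic_of=clinic_of,
        attribute_names=attr_names,
    )
    return table, truth
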