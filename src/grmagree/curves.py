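"""Expected-score tracelines and patient-clinic difference curves.

For every item the posterior of the expected score E[Y | theta] is evaluated
on a theta grid: expected scores are computed draw by draw and then averaged
(mean of the nonlinear transform, not the transform of the parameter means),
with empirical 2.5/97.5% bands.  The patient-side summary averages the
attribute-item curves; per-clinic difference curves subtract each clinic's
curve from the patient average, so positive values mean the clinic
underestimates relative to patients, and their across-clinic mean is the
headline "thick line".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import ItemInfo, ROLE_ATTRIBUTE, ROLE_CLINIC
from .grm import ItemParams, category_probs
from .inference import PosteriorDraws


@dataclass(frozen=True)
class ThetaGrid:
    """Evaluation grid for the latent trait, in standard-deviation units."""

    lo: float = -3.0
    hi: float = 3.0
    step: float = 0.05

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.step > 0):
            raise ValueError("need lo < hi and step > 0")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)


@dataclass
class CurveSet:
    """Posterior expected-score curves: per item, mean and 95% band on a grid."""

    grid: ThetaGrid
    items: list[ItemInfo]
    mean: np.ndarray   # (n_items, n_grid)
    lo95: np.ndarray
    hi95: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: item_label, role, theta, mean, lo95, hi95."""
        g = self.grid.values
        rows = []
        for j, item in enumerate(self.items):
            rows.append(pd.DataFrame({
                "item_label": item.item_id, "role": item.role, "theta": g,
                "mean": self.mean[j], "lo95": self.lo95[j], "hi95": self.hi95[j],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class DifferenceCurves:
    """Patient-average minus per-clinic expected score; positive values =
    clinic underestimation."""

    grid: ThetaGrid
    clinic_labels: list[str]
    per_clinic: np.ndarray       # (n_clinics, n_grid)
    mean_difference: np.ndarray  # (n_grid,)

    def to_frame(self) -> pd.DataFrame:
        g = self.grid.values
        rows = [pd.DataFrame({
            "item_label": lab, "theta": g, "difference": self.per_clinic[c]})
            for c, lab in enumerate(self.clinic_labels)]
        rows.append(pd.DataFrame({
            "item_label": "mean", "theta": g, "difference": self.mean_difference}))
        return pd.concat(rows, ignore_index=True)


def _expected_scores_by_draw(alpha: np.ndarray, kappa: np.ndarray,
                             grid: np.ndarray) -> np.ndarray:
    """(n_draws, n_grid) expected scores for one item's draw arrays."""
    z = alpha[:, None, None] * grid[None, :, None] - kappa[:, None, :]
    return expit(z).sum(axis=-1)


def item_curves(draws: PosteriorDraws, grid: ThetaGrid = ThetaGrid()) -> CurveSet:
    """Posterior expected-score curve (mean and 95% band) for every item."""
    g = grid.values
    if g.size == 0:
        raise ValueError("empty theta grid")
    p = len(draws.items)
    mean = np.empty((p, g.size))
    lo = np.empty((p, g.size))
    hi = np.empty((p, g.size))
    for j in range(p):
        es = _expected_scores_by_draw(
            draws.alpha_flat()[:, j], draws.kappa_flat(j), g)
        mean[j] = es.mean(axis=0)
        lo[j], hi[j] = np.quantile(es, [0.025, 0.975], axis=0)
    return CurveSet(grid=grid, items=list(draws.items), mean=mean,
                    lo95=lo, hi95=hi)


def patient_average_curve(curves: CurveSet) -> np.ndarray:
    """Unweighted mean of the patient-attribute item curves at each grid point."""
    idx = [j for j, it in enumerate(curves.items) if it.role == ROLE_ATTRIBUTE]
    if not idx:
        raise ValueError("no patient_attribute items in curve set")
    return curves.mean[idx].mean(axis=0)


def difference_curves(curves: CurveSet) -> DifferenceCurves:
    """Patient-average minus clinic curves, plus their across-clinic mean."""
    cidx = [j for j, it in enumerate(curves.items) if it.role == ROLE_CLINIC]
    if not cidx:
        raise ValueError("no clinic items in curve set")
    pat = patient_average_curve(curves)
    per_clinic = pat[None, :] - curves.mean[cidx]
    return DifferenceCurves(
        grid=curves.grid,
        clinic_labels=[curves.items[j].item_id for j in cidx],
        per_clinic=per_clinic,
        mean_difference=per_clinic.mean(axis=0),
    )


def place_patient(
    response_pattern: dict[str, int],
    items: list[tuple[ItemInfo, ItemParams]],
    grid_step: float = 0.001,
    grid_half_width: float = 6.0,
) -> float:
    """Posterior-mean theta of one hypothetical patient by quadrature.

    Item parameters are fixed (typically at their posterior means); the
    single-patient posterior density over theta is the standard-normal prior
    times the likelihood of the given responses, integrated on a fine grid.
    Missing items are simply absent from ``response_pattern``; an empty
    pattern returns the prior mean 0.0 with a warning.
    """
    pattern = {k: v for k, v in response_pattern.items() if v is not None}
    if not pattern:
        warnings.warn("empty response pattern: returning prior mean 0.0")
        return 0.0
    known = {info.item_id: (info, params) for info, params in items}
    for item_id in pattern:
        if item_id not in known:
            raise ValueError(f"unknown item {item_id!r} in response pattern")

    g = np.arange(-grid_half_width, grid_half_width + grid_step / 2, grid_step)
    log_w = norm.logpdf(g)
    for item_id, y in pattern.items():
        info, params = known[item_id]
        if not 0 <= y < info.n_categories:
            raise ValueError(
                f"response {y} for item {item_id!r} outside 0..{info.n_categories - 1}")
        probs = category_probs(params, g)[:, y]
        log_w = log_w + np.log(np.maximum(probs, 1e-300))
    w = np.exp(log_w - log_w.max())
    return float((g * w).sum() / w.sum())
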