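"""Graded response model probability machinery.

Samejima's graded response model in slope-intercept form with a logistic
link: for an item with K ordered categories 0..K-1, discrimination
``alpha > 0`` and strictly increasing thresholds ``kappa_1 < ... <
kappa_{K-1}``,

    P(Y >= k | theta) = logistic(alpha * theta - kappa_k),   k = 1..K-1,

with P(Y >= 0) = 1 and P(Y >= K) = 0.  Category probabilities are adjacent
differences of the cumulative curve and the expected item score is

    E[Y | theta] = sum_k k P(Y = k | theta) = sum_{k>=1} P(Y >= k | theta).

The latent trait theta carries a fixed standard-normal prior (this fixes the
location and scale of the latent metric); discriminations get a normal prior
truncated to alpha > 0 and thresholds independent normal priors restricted
to the ordered region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_ndtr
from scipy.stats import norm

from .data import RatingsTable

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class ItemParams:
    """One rater-item's GRM parameters: discrimination and ordered thresholds."""

    alpha: float
    kappa: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", tuple(float(k) for k in self.kappa))
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if np.any(np.diff(self.kappa) <= 0):
            raise ValueError(f"kappa must be strictly increasing, got {self.kappa}")

    @property
    def n_categories(self) -> int:
        return len(self.kappa) + 1


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors: alpha ~ N(mean, sd) truncated to (0, inf),
    each kappa ~ N(mean, sd) on the ordered region, theta ~ N(0, 1) fixed."""

    alpha_mean: float = 1.0
    alpha_sd: float = 2.5
    kappa_mean: float = 0.0
    kappa_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.alpha_sd <= 0 or self.kappa_sd <= 0:
            raise ValueError("prior standard deviations must be > 0")

    def log_prior_alpha(self, alpha) -> np.ndarray:
        """Log density of the positive-truncated normal prior on alpha."""
        alpha = np.asarray(alpha, dtype=float)
        out = np.where(
            alpha > 0,
            norm.logpdf(alpha, self.alpha_mean, self.alpha_sd)
            - log_ndtr(self.alpha_mean / self.alpha_sd),
            -np.inf,
        )
        return out

    def log_prior_kappa(self, kappa) -> float:
        """Log density (up to the ordering-region constant) of the kappa prior."""
        kappa = np.asarray(kappa, dtype=float)
        if kappa.size > 1 and np.any(np.diff(kappa) <= 0):
            return -np.inf
        return float(norm.logpdf(kappa, self.kappa_mean, self.kappa_sd).sum())


def _check_cut(item: ItemParams, k: int) -> None:
    if not 1 <= k <= item.n_categories - 1:
        raise ValueError(
            f"cut index {k} out of range 1..{item.n_categories - 1}"
        )


def cumulative_prob(item: ItemParams, k: int, theta) -> np.ndarray:
    """P(Y >= k | theta) for cut index k in 1..K-1."""
    _check_cut(item, k)
    theta = np.asarray(theta, dtype=float)
    return expit(item.alpha * theta - item.kappa[k - 1])


def category_probs(item: ItemParams, theta) -> np.ndarray:
    """Probability of each category 0..K-1; shape ``theta.shape + (K,)``."""
    theta = np.asarray(theta, dtype=float)
    z = item.alpha * theta[..., None] - np.asarray(item.kappa)
    cum = expit(z)                                    # P(Y>=1..K-1)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    upper = np.concatenate([ones, cum], axis=-1)      # P(Y>=0..K-1)
    lower = np.concatenate([cum, zeros], axis=-1)     # P(Y>=1..K)
    return upper - lower


def expected_score(item: ItemParams, theta) -> np.ndarray:
    """E[Y | theta] on the 0..K-1 grade scale (sum of cumulative curves)."""
    theta = np.asarray(theta, dtype=float)
    z = item.alpha * theta[..., None] - np.asarray(item.kappa)
    return expit(z).sum(axis=-1)


def log_posterior(
    table: RatingsTable,
    items: list[ItemParams],
    thetas,
    priors: PriorSpec = PriorSpec(),
) -> float:
    """Observed-data log posterior density (up to an additive constant).

    Sum over non-missing records of ``log P(Y = y | theta_i)`` for the
    record's item, plus log priors on every alpha, kappa and theta.  Missing
    responses (NOT_RATED or SKIPPED) contribute nothing: the posterior is
    updated from available data only.
    """
    thetas = np.asarray(thetas, dtype=float)
    if len(items) != table.n_items:
        raise ValueError(
            f"{len(items)} parameter sets for {table.n_items} items"
        )
    if thetas.shape != (table.n_patients,):
        raise ValueError(
            f"thetas shape {thetas.shape} != ({table.n_patients},)"
        )
    for item_info, params in zip(table.items, items):
        if params.n_categories != item_info.n_categories:
            raise ValueError(
                f"item {item_info.item_id!r}: {params.n_categories} categories "
                f"in params vs {item_info.n_categories} declared"
            )

    total = 0.0
    for j, params in enumerate(items):
        col = table.responses[:, j]
        obs = col >= 0
        if not obs.any():
            continue
        probs = category_probs(params, thetas[obs])
        p_obs = probs[np.arange(obs.sum()), col[obs]]
        total += float(np.log(np.maximum(p_obs, _LOG_FLOOR)).sum())

    for params in items:
        total += float(priors.log_prior_alpha(params.alpha))
        total += priors.log_prior_kappa(params.kappa)
    total += float(norm.logpdf(thetas).sum())
    return total
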