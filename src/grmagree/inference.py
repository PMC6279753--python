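"""Bayesian estimation of the graded response model by MCMC.

The sampler is an adaptive random-walk Metropolis-within-Gibbs targeting the
observed-data posterior of :func:`grmagree.grm.log_posterior`:

* one block per patient latent trait ``theta_i`` (all updated in a single
  vectorised sweep -- the thetas are conditionally independent given the
  item parameters, so simultaneous independent accept/reject decisions are a
  valid Gibbs sweep);
* one block per item, proposing ``(alpha, kappa_1..kappa_{K-1})`` jointly
  with a symmetric Gaussian random walk.  Proposals with ``alpha <= 0`` or
  unordered thresholds fall outside the prior's support and are rejected,
  which is how positivity and threshold ordering are enforced.

Step sizes are tuned per block toward ~0.44 acceptance during the
adaptation phase only, then frozen, so the post-adaptation chain is a valid
fixed-kernel Markov chain.  The retained sample honours the configured
adaptation / burn-in / thinning schedule exactly, and a fixed seed
reproduces draws bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import RatingsTable, ItemInfo, ROLE_CLINIC
from .grm import ItemParams, PriorSpec

_TARGET_ACCEPT = 0.44
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule.  Defaults follow the common long-schedule convention
    of 1000 adaptation + 5000 burn-in iterations with 8000 retained draws
    after thinning by 10."""

    n_adapt: int = 1000
    n_burn: int = 5000
    n_keep: int = 8000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_adapt, self.n_burn, self.n_keep, self.n_chains) <= 0:
            raise ValueError("all iteration counts and n_chains must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples for every item parameter and patient theta.

    ``alpha`` has shape (n_chains, n_keep, n_items), ``kappa[j]`` shape
    (n_chains, n_keep, K_j - 1), ``theta`` shape (n_chains, n_keep,
    n_patients).
    """

    items: list[ItemInfo]
    patients: list[str]
    alpha: np.ndarray
    kappa: list[np.ndarray]
    theta: np.ndarray
    config: McmcConfig
    accept_rates: dict = field(default_factory=dict)
    wide_posterior_items: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    def alpha_flat(self) -> np.ndarray:
        return self.alpha.reshape(-1, self.alpha.shape[-1])

    def kappa_flat(self, j: int) -> np.ndarray:
        return self.kappa[j].reshape(-1, self.kappa[j].shape[-1])

    def theta_flat(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def item_params_mean(self) -> list[ItemParams]:
        """Posterior-mean ItemParams per item (threshold means stay ordered
        because every stored draw is ordered)."""
        out = []
        for j in range(len(self.items)):
            out.append(ItemParams(
                float(self.alpha_flat()[:, j].mean()),
                tuple(self.kappa_flat(j).mean(axis=0)),
            ))
        return out

    def param_dict(self, include_theta: bool = True) -> dict[str, np.ndarray]:
        """Named scalar-parameter arrays of shape (n_chains, n_keep)."""
        out: dict[str, np.ndarray] = {}
        for j, item in enumerate(self.items):
            out[f"alpha[{item.item_id}]"] = self.alpha[:, :, j]
            for k in range(item.n_categories - 1):
                out[f"kappa[{item.item_id},{k + 1}]"] = self.kappa[j][:, :, k]
        if include_theta:
            for i, pid in enumerate(self.patients):
                out[f"theta[{pid}]"] = self.theta[:, :, i]
        return out

    def to_dataframe(self, include_theta: bool = True) -> pd.DataFrame:
        """One row per retained draw (chains stacked), named columns."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.alpha.shape[1]),
                "draw": np.tile(np.arange(self.alpha.shape[1]), self.n_chains)}
        for name, arr in self.param_dict(include_theta).items():
            cols[name] = arr.reshape(-1)
        return pd.DataFrame(cols)

    # -- plain-text persistence (draws csv + json metadata) ---------------

    def save(self, prefix: str) -> None:
        self.to_dataframe().to_csv(f"{prefix}.draws.csv", index=False)
        meta = {
            "items": [asdict(it) for it in self.items],
            "patients": self.patients,
            "config": asdict(self.config),
            "accept_rates": {k: float(np.mean(v)) for k, v in self.accept_rates.items()},
            "wide_posterior_items": self.wide_posterior_items,
        }
        with open(f"{prefix}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str) -> "PosteriorDraws":
        df = pd.read_csv(f"{prefix}.draws.csv")
        with open(f"{prefix}.meta.json") as fh:
            meta = json.load(fh)
        items = [ItemInfo(**d) for d in meta["items"]]
        patients = [str(p) for p in meta["patients"]]
        config = McmcConfig(**meta["config"])
        n_chains = int(df["chain"].max()) + 1
        n_keep = len(df) // n_chains

        def grab(name: str) -> np.ndarray:
            return df[name].to_numpy().reshape(n_chains, n_keep)

        alpha = np.stack([grab(f"alpha[{it.item_id}]") for it in items], axis=-1)
        kappa = [
            np.stack([grab(f"kappa[{it.item_id},{k + 1}]")
                      for k in range(it.n_categories - 1)], axis=-1)
            for it in items
        ]
        theta_cols = [c for c in df.columns if c.startswith("theta[")]
        theta = np.stack([grab(c) for c in theta_cols], axis=-1)
        return cls(items=items, patients=patients, alpha=alpha, kappa=kappa,
                   theta=theta, config=config,
                   wide_posterior_items=meta.get("wide_posterior_items", []))


@dataclass
class Diagnostics:
    """Split-R-hat and effective sample size per scalar parameter."""

    rhat: pd.Series
    ess: pd.Series
    n_bad_rhat: int
    rhat_available: bool
    threshold: float = 1.05


# ---------------------------------------------------------------------------
# likelihood helpers on the internal packed representation
# ---------------------------------------------------------------------------

def _pad(kappa: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], kappa, [np.inf]))


def _item_loglik(alpha: float, kp: np.ndarray, thetas: np.ndarray,
                 y: np.ndarray) -> np.ndarray:
    """Per-response log P(Y=y|theta) for one item; kp is the padded kappa."""
    z = alpha * thetas
    p = expit(z - kp[y]) - expit(z - kp[y + 1])
    return np.log(np.maximum(p, _LOG_FLOOR))


def _init_kappa(y: np.ndarray, n_categories: int) -> np.ndarray:
    """Data-informed start: thresholds matching the observed cumulative
    proportions at alpha=1, theta=0, forced strictly increasing."""
    kap = np.empty(n_categories - 1)
    for k in range(1, n_categories):
        phat = float(np.clip((y >= k).mean(), 0.02, 0.98))
        kap[k - 1] = -logit(phat)
    for k in range(1, len(kap)):   # enforce strict ordering
        kap[k] = max(kap[k], kap[k - 1] + 0.1)
    return kap


def fit_grm(
    table: RatingsTable,
    priors: PriorSpec = PriorSpec(),
    config: McmcConfig = McmcConfig(),
) -> PosteriorDraws:
    """Sample the joint posterior of all item parameters and patient thetas.

    Items with zero observed responses are dropped with a warning; items
    observed in a single category are retained but flagged (their thresholds
    are informed mostly by the prior).  Missing responses contribute nothing
    to the likelihood.
    """
    if table.n_patients < 2:
        raise ValueError("need at least 2 patients")

    keep_idx = [j for j in range(table.n_items)
                if (table.responses[:, j] >= 0).any()]
    dropped = [table.items[j].item_id for j in range(table.n_items)
               if j not in keep_idx]
    if dropped:
        warnings.warn(f"dropping items with no observed responses: {dropped}")
    if not keep_idx:
        raise ValueError("no item has any observed response")

    items = [table.items[j] for j in keep_idx]
    n, p = table.n_patients, len(items)

    obs_idx: list[np.ndarray] = []
    obs_y: list[np.ndarray] = []
    wide: list[str] = []
    for j_out, j in enumerate(keep_idx):
        col = table.responses[:, j]
        mask = col >= 0
        obs_idx.append(np.flatnonzero(mask))
        obs_y.append(col[mask].astype(np.int64))
        if np.unique(obs_y[-1]).size == 1:
            wide.append(items[j_out].item_id)
    if wide:
        warnings.warn(
            f"items observed in a single category (posterior driven by the "
            f"prior, expect wide intervals): {wide}"
        )

    cfg = config
    n_iter = cfg.n_adapt + cfg.n_burn + cfg.n_keep * cfg.thin

    alpha_store = np.empty((cfg.n_chains, cfg.n_keep, p))
    kappa_store = [np.empty((cfg.n_chains, cfg.n_keep, it.n_categories - 1))
                   for it in items]
    theta_store = np.empty((cfg.n_chains, cfg.n_keep, n))
    acc_theta = np.zeros(cfg.n_chains)
    acc_items = np.zeros((cfg.n_chains, p))

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([int(cfg.seed), chain])

        theta = np.zeros(n)
        alpha = np.full(p, 1.0)
        kappa = [_init_kappa(obs_y[j], items[j].n_categories) for j in range(p)]
        kp = [_pad(k) for k in kappa]

        log_s_theta = np.full(n, np.log(0.8))
        log_s_item = np.full(p, np.log(0.3))

        n_acc_theta = 0.0
        n_acc_item = np.zeros(p)
        n_count = 0

        kept = 0
        for t in range(n_iter):
            adapting = t < cfg.n_adapt
            gamma = min(1.0, 5.0 / (t + 1) ** 0.6) if adapting else 0.0

            # ---- theta sweep (vectorised over patients) -----------------
            prop = theta + np.exp(log_s_theta) * rng.standard_normal(n)
            ll_cur = np.zeros(n)
            ll_prop = np.zeros(n)
            for j in range(p):
                idx, y = obs_idx[j], obs_y[j]
                ll_cur[idx] += _item_loglik(alpha[j], kp[j], theta[idx], y)
                ll_prop[idx] += _item_loglik(alpha[j], kp[j], prop[idx], y)
            logr = ll_prop - ll_cur + 0.5 * (theta ** 2 - prop ** 2)
            accept = np.log(rng.random(n)) < logr
            theta = np.where(accept, prop, theta)
            if adapting:
                log_s_theta += gamma * (accept.astype(float) - _TARGET_ACCEPT)

            sampling = t >= cfg.n_adapt + cfg.n_burn

            # ---- item sweeps --------------------------------------------
            for j in range(p):
                idx, y = obs_idx[j], obs_y[j]
                s = np.exp(log_s_item[j])
                a_prop = alpha[j] + s * rng.standard_normal()
                k_prop = kappa[j] + s * rng.standard_normal(kappa[j].size)
                ok = a_prop > 0 and (k_prop.size < 2 or np.all(np.diff(k_prop) > 0))
                acc = False
                if ok:
                    th = theta[idx]
                    cur = (_item_loglik(alpha[j], kp[j], th, y).sum()
                           - 0.5 * ((alpha[j] - priors.alpha_mean) / priors.alpha_sd) ** 2
                           - 0.5 * (((kappa[j] - priors.kappa_mean) / priors.kappa_sd) ** 2).sum())
                    kp_prop = _pad(k_prop)
                    new = (_item_loglik(a_prop, kp_prop, th, y).sum()
                           - 0.5 * ((a_prop - priors.alpha_mean) / priors.alpha_sd) ** 2
                           - 0.5 * (((k_prop - priors.kappa_mean) / priors.kappa_sd) ** 2).sum())
                    if np.log(rng.random()) < new - cur:
                        alpha[j] = a_prop
                        kappa[j] = k_prop
                        kp[j] = kp_prop
                        acc = True
                if adapting:
                    log_s_item[j] += gamma * (float(acc) - _TARGET_ACCEPT)
                elif sampling:
                    n_acc_item[j] += float(acc)

            if sampling:
                n_acc_theta += accept.mean()
                n_count += 1
                post = t - (cfg.n_adapt + cfg.n_burn)
                if (post + 1) % cfg.thin == 0:
                    alpha_store[chain, kept] = alpha
                    for j in range(p):
                        kappa_store[j][chain, kept] = kappa[j]
                    theta_store[chain, kept] = theta
                    kept += 1
        assert kept == cfg.n_keep, (kept, cfg.n_keep)
        acc_theta[chain] = n_acc_theta / max(n_count, 1)
        acc_items[chain] = n_acc_item / max(n_count, 1)

    return PosteriorDraws(
        items=items,
        patients=list(table.patients),
        alpha=alpha_store,
        kappa=kappa_store,
        theta=theta_store,
        config=cfg,
        accept_rates={"theta": acc_theta, "items": acc_items},
        wide_posterior_items=wide,
    )


# ---------------------------------------------------------------------------
# posterior summaries and convergence diagnostics
# ---------------------------------------------------------------------------

def summarize(draws: PosteriorDraws, include_theta: bool = False) -> pd.DataFrame:
    """Posterior mean, sd and central 95% interval per scalar parameter."""
    rows = {}
    for name, arr in draws.param_dict(include_theta).items():
        flat = arr.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows[name] = {"mean": flat.mean(), "sd": flat.std(ddof=1),
                      "q2.5": lo, "q97.5": hi}
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    return out


def diagnose(draws: PosteriorDraws, include_theta: bool = False,
             threshold: float = 1.05) -> Diagnostics:
    """Split-R-hat and effective sample size via arviz.

    With a single chain, R-hat is flagged as unavailable (split-R-hat on one
    chain halves it internally, but cross-chain mixing cannot be assessed).
    """
    import arviz as az

    params = draws.param_dict(include_theta)
    idata = az.from_dict(posterior={k: v for k, v in params.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata, method="split")
        ess_ds = az.ess(idata, method="bulk")
    rhat = pd.Series({k: float(rhat_ds[k].values) for k in params})
    ess = pd.Series({k: float(ess_ds[k].values) for k in params})
    available = draws.n_chains >= 2
    n_bad = int((rhat > threshold).sum()) if available else 0
    return Diagnostics(rhat=rhat, ess=ess, n_bad_rhat=n_bad,
                       rhat_available=available, threshold=threshold)
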