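"""MCMC contract tests: schedule bookkeeping, determinism, summaries,
diagnostics and small-scale parameter recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from grmagree import (
    ItemParams, McmcConfig, SimConfig, fit_grm, generate, summarize, diagnose,
)
from grmagree.inference import PosteriorDraws
from conftest import make_table


def _quiet_fit(table, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_grm(table, config=config)


class TestSchedule:
    def test_exact_retained_draw_count(self):
        table, _ = generate(SimConfig(n_patients=30, n_clinics=2, seed=1))
        cfg = McmcConfig(n_adapt=100, n_burn=200, n_keep=400, thin=2,
                         n_chains=1, seed=5)
        draws = _quiet_fit(table, cfg)
        assert draws.alpha.shape[:2] == (1, 400)
        assert draws.n_draws == 400

    def test_total_draws_scale_with_chains(self, small_fit):
        _, _, draws = small_fit
        assert draws.n_draws == draws.config.n_keep * draws.config.n_chains

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
        with pytest.raises(ValueError):
            McmcConfig(n_keep=0)


class TestDeterminism:
    def test_same_seed_reproduces_draws_bitwise(self):
        table, _ = generate(SimConfig(n_patients=40, n_clinics=2, seed=2))
        cfg = McmcConfig(n_adapt=50, n_burn=50, n_keep=100, thin=1,
                         n_chains=2, seed=123)
        d1 = _quiet_fit(table, cfg)
        d2 = _quiet_fit(table, cfg)
        assert np.array_equal(d1.alpha, d2.alpha)
        assert np.array_equal(d1.theta, d2.theta)
        for k1, k2 in zip(d1.kappa, d2.kappa):
            assert np.array_equal(k1, k2)

    def test_not_rated_padding_leaves_draws_unchanged(self):
        # an extra never-observed clinic item is dropped before sampling, so
        # the random stream and hence every draw is identical
        rng = np.random.default_rng(0)
        resp = rng.integers(0, 5, (30, 3)).astype(np.int16)
        t1 = make_table(resp, roles=["patient_attribute"] * 2 + ["clinic"])
        padded = np.hstack([resp, np.full((30, 1), -1, dtype=np.int16)])
        t2 = make_table(padded, roles=["patient_attribute"] * 2 + ["clinic"] * 2)
        cfg = McmcConfig(n_adapt=50, n_burn=50, n_keep=100, thin=1,
                         n_chains=1, seed=9)
        d1 = _quiet_fit(t1, cfg)
        d2 = _quiet_fit(t2, cfg)
        assert [i.item_id for i in d1.items] == [i.item_id for i in d2.items][:3]
        assert np.array_equal(d1.alpha, d2.alpha[:, :, :3])
        assert np.array_equal(d1.theta, d2.theta)


class TestStructure:
    def test_kappa_draws_strictly_increasing(self, small_fit):
        _, _, draws = small_fit
        for k in draws.kappa:
            assert (np.diff(k, axis=-1) > 0).all()

    def test_zero_observation_item_dropped_with_warning(self):
        resp = np.array([[1, -1], [2, -1], [0, -1]], dtype=np.int16)
        t = make_table(resp, roles=["patient_attribute", "clinic"])
        cfg = McmcConfig(n_adapt=20, n_burn=20, n_keep=30, thin=1,
                         n_chains=1, seed=1)
        with pytest.warns(UserWarning, match="no observed responses"):
            draws = fit_grm(t, config=cfg)
        assert [i.item_id for i in draws.items] == ["attr0"]

    def test_single_category_item_flagged(self):
        resp = np.array([[1, 2], [2, 2], [0, 2]], dtype=np.int16)
        t = make_table(resp, roles=["patient_attribute", "clinic"])
        cfg = McmcConfig(n_adapt=20, n_burn=20, n_keep=30, thin=1,
                         n_chains=1, seed=1)
        with pytest.warns(UserWarning, match="single category"):
            draws = fit_grm(t, config=cfg)
        assert draws.wide_posterior_items == ["clinic1"]

    def test_all_missing_patient_shrinks_to_prior(self):
        rng = np.random.default_rng(4)
        resp = rng.integers(0, 5, (120, 3)).astype(np.int16)
        resp[0] = -1  # patient with no data at all
        t = make_table(resp)
        cfg = McmcConfig(n_adapt=300, n_burn=300, n_keep=2000, thin=1,
                         n_chains=1, seed=3)
        draws = _quiet_fit(t, cfg)
        th = draws.theta_flat()[:, 0]
        assert abs(th.mean()) < 0.1
        assert abs(th.std(ddof=1) - 1.0) < 0.1


class TestRecovery:
    def test_posterior_mean_alpha_near_truth(self):
        truth = ItemParams(2.0, (-1.0, 0.0, 1.0, 2.0))
        config = SimConfig(n_patients=500, n_clinics=1, n_attributes=3,
                           patient_items=(truth,) * 3,
                           clinic_items=(truth,), skip_rule=False, seed=17)
        table, _ = generate(config)
        cfg = McmcConfig(n_adapt=300, n_burn=400, n_keep=800, thin=1,
                         n_chains=1, seed=21)
        draws = _quiet_fit(table, cfg)
        s = summarize(draws)
        for item in draws.items[:3]:
            assert s.loc[f"alpha[{item.item_id}]", "mean"] == \
                pytest.approx(2.0, abs=0.3)


class TestSummarize:
    def test_constant_draws_zero_width_interval(self):
        d = _dummy_draws(np.full((2, 50), 3.25))
        s = summarize(d)
        row = s.loc["alpha[attr0]"]
        assert row["mean"] == 3.25
        assert row["q2.5"] == row["q97.5"] == 3.25

    def test_arithmetic_mean_of_1_to_100(self):
        d = _dummy_draws(np.arange(1.0, 101.0).reshape(1, 100))
        assert summarize(d).loc["alpha[attr0]", "mean"] == pytest.approx(50.5)

    def test_matches_brute_force_quantiles(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(2, 200))
        d = _dummy_draws(vals)
        row = summarize(d).loc["alpha[attr0]"]
        flat = np.sort(vals.reshape(-1))
        assert row["q2.5"] == pytest.approx(np.quantile(flat, 0.025), abs=1e-12)
        assert row["q97.5"] == pytest.approx(np.quantile(flat, 0.975), abs=1e-12)


class TestDiagnose:
    def test_well_mixed_chains_have_rhat_near_one(self):
        rng = np.random.default_rng(7)
        d = _dummy_draws(rng.standard_normal((2, 500)))
        diag = diagnose(d)
        assert diag.rhat_available
        assert diag.rhat["alpha[attr0]"] == pytest.approx(1.0, abs=0.02)
        assert diag.n_bad_rhat == 0

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((2, 500))
        vals[1] += 30.0
        diag = diagnose(_dummy_draws(vals))
        assert diag.rhat["alpha[attr0]"] > 2.0
        assert diag.n_bad_rhat >= 1

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(7)
        diag = diagnose(_dummy_draws(rng.standard_normal((1, 100))))
        assert not diag.rhat_available

    def test_matches_textbook_split_rhat_formula(self):
        rng = np.random.default_rng(11)
        vals = rng.standard_normal((2, 400)) + np.array([[0.0], [0.3]])
        diag = diagnose(_dummy_draws(vals))

        # independent split-Rhat oracle: split each chain in half, compare
        # between- and within-half variances
        halves = vals.reshape(4, 200)
        n = halves.shape[1]
        W = halves.var(ddof=1, axis=1).mean()
        B = n * halves.mean(axis=1).var(ddof=1)
        var_plus = (n - 1) / n * W + B / n
        expected = np.sqrt(var_plus / W)
        assert diag.rhat["alpha[attr0]"] == pytest.approx(expected, abs=1e-6)


def _dummy_draws(alpha_vals: np.ndarray) -> PosteriorDraws:
    """Single-item PosteriorDraws wrapper around a given alpha draw array."""
    from grmagree import ItemInfo

    alpha_vals = np.asarray(alpha_vals, dtype=float)
    n_chains, n_keep = alpha_vals.shape
    kappa = np.tile(np.array([-1.0, 0.0, 1.0, 2.0]), (n_chains, n_keep, 1))
    return PosteriorDraws(
        items=[ItemInfo("attr0", 5, "patient_attribute")],
        patients=["p0"],
        alpha=alpha_vals[:, :, None],
        kappa=[kappa],
        theta=np.zeros((n_chains, n_keep, 1)),
        config=McmcConfig(n_adapt=1, n_burn=1, n_keep=n_keep,
                          thin=1, n_chains=n_chains, seed=0),
    )
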