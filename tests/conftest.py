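import numpy as np
import pytest

from grmagree import (
    ItemInfo, ItemParams, McmcConfig, RatingsTable, SimConfig, fit_grm,
    generate, NOT_RATED,
)


def make_table(responses, roles=None, n_categories=5, ae_name="pain",
               item_ids=None, patients=None):
    """Small RatingsTable from a dense int matrix (negatives = missing)."""
    responses = np.asarray(responses, dtype=np.int16)
    n, p = responses.shape
    if roles is None:
        roles = ["patient_attribute"] * p
    if item_ids is None:
        item_ids = [
            f"attr{j}" if r == "patient_attribute" else f"clinic{j}"
            for j, r in enumerate(roles)
        ]
    items = [ItemInfo(i, n_categories, r) for i, r in zip(item_ids, roles)]
    if patients is None:
        patients = [f"p{i:03d}" for i in range(n)]
    return RatingsTable(ae_name=ae_name, patients=patients, items=items,
                        responses=responses)


@pytest.fixture(scope="session")
def small_fit():
    """One shared short fit of a small synthetic dataset (2 chains)."""
    import warnings

    config = SimConfig(n_patients=150, n_clinics=3, seed=42)
    table, truth = generate(config)
    mc = McmcConfig(n_adapt=200, n_burn=200, n_keep=300, thin=1,
                    n_chains=2, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_grm(table, config=mc)
    return table, truth, draws


@pytest.fixture
def pain_params():
    """Published-magnitude severity-like item parameters."""
    return ItemParams(5.69, (-6.46, 1.21, 5.48, 9.10))
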