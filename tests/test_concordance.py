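"""Traditional concordance metrics, checked against brute-force pair
expansion and published pain-table values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import cohen_kappa_score

from grmagree import (
    ContingencyTable, conditional_grade_table, crosstab, diagonal_count,
    pain_conditional_counts, pain_severity_crosstab, percent_agreement,
    spearman_from_table, weighted_kappa, concordance_metrics,
)
from grmagree.concordance import DegenerateTableError
from conftest import make_table


def random_tables():
    return st.builds(
        lambda counts, r0, c0: ContingencyTable(
            np.asarray(counts),
            tuple(range(r0, r0 + len(counts))),
            tuple(range(c0, c0 + len(counts[0])))),
        st.lists(st.lists(st.integers(0, 20), min_size=3, max_size=3),
                 min_size=3, max_size=4),
        st.integers(0, 1), st.integers(0, 1),
    )


class TestCrosstab:
    def test_expanded_pain_pairs_rebuild_the_table(self):
        ct = pain_severity_crosstab()
        a, b = ct.to_pairs()
        assert len(a) == 525
        rebuilt = crosstab(list(zip(a, b)), ct.row_labels, ct.col_labels)
        assert np.array_equal(rebuilt.counts, ct.counts)

    def test_empty_input_with_labels_gives_zero_table(self):
        ct = crosstab([], (0, 1), (0, 1))
        assert ct.n == 0
        assert (ct.counts == 0).all()

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(1)
        pairs = list(zip(rng.integers(0, 3, 10), rng.integers(0, 4, 10)))
        ct = crosstab(pairs, (0, 1, 2), (0, 1, 2, 3))
        for i in range(3):
            for j in range(4):
                assert ct.counts[i, j] == sum(p == (i, j) for p in pairs)

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError, match="outside declared"):
            crosstab([(5, 0)], (0, 1), (0, 1))


class TestPercentAgreement:
    def test_published_pain_table_value(self):
        ct = pain_severity_crosstab()
        assert percent_agreement(ct) == pytest.approx(132 / 525)
        assert round(percent_agreement(ct), 2) == 0.25

    def test_identity_table_is_perfect(self):
        ct = ContingencyTable(np.eye(4, dtype=int) * 7, range(4), range(4))
        assert percent_agreement(ct) == 1.0

    def test_two_by_two_half(self):
        ct = ContingencyTable([[1, 1], [1, 1]], (0, 1), (0, 1))
        assert percent_agreement(ct) == 0.5

    def test_empty_table_undefined(self):
        ct = ContingencyTable([[0, 0], [0, 0]], (0, 1), (0, 1))
        with pytest.raises(DegenerateTableError):
            percent_agreement(ct)

    def test_equals_diagonal_over_n(self):
        ct = pain_severity_crosstab()
        assert percent_agreement(ct) == diagonal_count(ct) / ct.n


class TestDiagonalCount:
    def test_published_pain_table_value(self):
        assert diagonal_count(pain_severity_crosstab()) == 132

    def test_zero_table(self):
        ct = ContingencyTable([[0, 0], [0, 0]], (0, 1), (0, 1))
        assert diagonal_count(ct) == 0

    def test_matches_brute_force_pair_scan(self):
        rng = np.random.default_rng(2)
        pairs = list(zip(rng.integers(0, 3, 50), rng.integers(0, 3, 50)))
        ct = crosstab(pairs, (0, 1, 2), (0, 1, 2))
        assert diagonal_count(ct) == sum(a == b for a, b in pairs)


class TestWeightedKappa:
    def test_published_pain_table_linear_value(self):
        ct = pain_severity_crosstab()
        assert round(weighted_kappa(ct, "linear"), 2) == 0.15

    def test_perfect_diagonal_is_one(self):
        ct = ContingencyTable(np.diag([3, 5, 2]), range(3), range(3))
        assert weighted_kappa(ct, "linear") == pytest.approx(1.0)
        assert weighted_kappa(ct, "quadratic") == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        # po=0.7, pe=0.5 -> (0.7-0.5)/(1-0.5) = 0.4
        ct = ContingencyTable([[40, 10], [20, 30]], (0, 1), (0, 1))
        assert weighted_kappa(ct, "linear") == pytest.approx(0.4)

    def test_degenerate_marginals_undefined(self):
        ct = ContingencyTable([[10, 0], [0, 0]], (0, 1), (0, 1))
        with pytest.raises(DegenerateTableError):
            weighted_kappa(ct)

    @settings(derandomize=True, max_examples=40)
    @given(random_tables(), st.sampled_from(["linear", "quadratic"]))
    def test_matches_sklearn_on_expanded_pairs(self, ct, scheme):
        a, b = ct.to_pairs()
        if ct.n == 0 or min(len(set(a)), len(set(b))) < 2:
            return
        labels = sorted(set(ct.row_labels) | set(ct.col_labels))
        expected = cohen_kappa_score(a, b, labels=labels, weights=scheme)
        if not np.isfinite(expected):
            return
        assert weighted_kappa(ct, scheme) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.lists(st.integers(0, 15), min_size=2, max_size=2),
                    min_size=2, max_size=2))
    def test_linear_equals_unweighted_on_2x2(self, counts):
        ct = ContingencyTable(np.asarray(counts), (0, 1), (0, 1))
        a, b = ct.to_pairs()
        if ct.n == 0 or min(len(set(a)), len(set(b))) < 2:
            return
        unweighted = cohen_kappa_score(a, b, labels=[0, 1])
        if not np.isfinite(unweighted):
            return
        try:
            kl = weighted_kappa(ct, "linear")
        except DegenerateTableError:
            return
        assert kl == pytest.approx(unweighted, abs=1e-12)


class TestSpearman:
    def test_published_pain_table_value(self):
        ct = pain_severity_crosstab()
        assert round(spearman_from_table(ct), 2) == 0.44

    def test_diagonal_table_perfect_correlation(self):
        ct = ContingencyTable(np.diag([4, 6]), (0, 1), (0, 1))
        assert spearman_from_table(ct) == pytest.approx(1.0)

    def test_constant_margin_undefined(self):
        ct = ContingencyTable([[3, 4]], (0,), (0, 1))
        with pytest.raises(DegenerateTableError):
            spearman_from_table(ct)

    @settings(derandomize=True, max_examples=40)
    @given(random_tables())
    def test_matches_scipy_on_expanded_pairs(self, ct):
        a, b = ct.to_pairs()
        if ct.n < 2 or min(len(set(a)), len(set(b))) < 2:
            return
        expected = spearmanr(a, b).statistic
        assert spearman_from_table(ct) == pytest.approx(expected, abs=1e-12)


class TestConcordanceMetrics:
    def test_scheme_tag_carried(self):
        res = concordance_metrics(pain_severity_crosstab(), "quadratic")
        assert res.kappa_scheme == "quadratic"
        assert res.n == 525

    @settings(derandomize=True, max_examples=20)
    @given(random_tables())
    def test_table_and_pair_routes_agree_exactly(self, ct):
        a, b = ct.to_pairs()
        if ct.n < 2 or min(len(set(a)), len(set(b))) < 2:
            return
        res = concordance_metrics(ct)
        assert res.percent_agreement == sum(x == y for x, y in zip(a, b)) / ct.n
        assert res.spearman_r == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)
        labels = sorted(set(ct.row_labels) | set(ct.col_labels))
        expected_k = cohen_kappa_score(a, b, labels=labels, weights="linear")
        if np.isfinite(expected_k):
            assert res.weighted_kappa == pytest.approx(expected_k, abs=1e-12)


class TestConditionalGradeTable:
    def _study_shaped_table(self):
        # patients whose three attributes all equal v, with clinician grades
        # mirroring the published conditional pain distribution
        rows, grades, clinics = [], [], []
        spec_counts = {1: [(1, 21), (2, 3)], 2: [(1, 27), (2, 8)],
                       3: [(1, 9), (2, 10), (3, 5)]}
        for v, pairs in spec_counts.items():
            for g, c in pairs:
                for _ in range(c):
                    rows.append([v, v, v])
                    grades.append(g)
        n = len(rows)
        resp = np.full((n, 3 + 1), -1, dtype=np.int16)
        resp[:, :3] = rows
        resp[:, 3] = grades
        return make_table(resp, roles=["patient_attribute"] * 3 + ["clinic"],
                          item_ids=["frequency", "severity", "interference",
                                    "clinic1"])

    def test_mirrors_published_conditional_distribution(self):
        t = self._study_shaped_table()
        out = conditional_grade_table(t, [1, 2, 3], grades=[1, 2, 3])
        assert out.loc[1].tolist() == [21, 3, 0]
        assert out.loc[2].tolist() == [27, 8, 0]
        assert out.loc[3].tolist() == [9, 10, 5]
        assert out.to_numpy().sum() == 83
        assert np.array_equal(out.to_numpy(),
                              pain_conditional_counts().to_numpy())

    def test_no_match_gives_zero_row(self):
        t = self._study_shaped_table()
        out = conditional_grade_table(t, [4], grades=[1, 2, 3])
        assert out.loc[4].tolist() == [0, 0, 0]

    def test_matches_brute_force_filter_and_tally(self):
        rng = np.random.default_rng(3)
        resp = np.hstack([
            rng.integers(0, 3, (60, 2)),
            rng.integers(0, 4, (60, 1)),
        ]).astype(np.int16)
        t = make_table(resp, roles=["patient_attribute"] * 2 + ["clinic"],
                       item_ids=["frequency", "severity", "clinic1"])
        out = conditional_grade_table(t, [0, 1, 2], grades=[0, 1, 2, 3])
        for v in (0, 1, 2):
            for g in (0, 1, 2, 3):
                brute = sum(
                    1 for i in range(60)
                    if resp[i, 0] == v and resp[i, 1] == v and resp[i, 2] == g)
                assert out.loc[v, g] == brute
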