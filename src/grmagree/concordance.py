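"""Traditional agreement statistics on paired ordinal grades.

All metrics operate on an R x C contingency table of two raters' grades
(rows: rater A categories, columns: rater B categories).  Rectangular
tables -- e.g. five patient severity categories against four observed
clinician grades -- are aligned by shared category labels for diagonal
statistics and zero-padded to a square over the union of labels for
weighted kappa.  Spearman's r uses midranks for ties, computed in closed
form from the table margins (equivalent to expanding the table to n pairs
and rank-correlating).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import RatingsTable


class DegenerateTableError(ValueError):
    """Metric undefined for this table (empty, or degenerate marginals)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two ordinal raters' grades."""

    counts: np.ndarray
    row_labels: tuple[int, ...]
    col_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if list(self.row_labels) != sorted(set(self.row_labels)) or \
           list(self.col_labels) != sorted(set(self.col_labels)):
            raise ValueError("labels must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def to_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand back to the n (grade_a, grade_b) pairs."""
        a, b = [], []
        for i, ra in enumerate(self.row_labels):
            for j, cb in enumerate(self.col_labels):
                c = int(self.counts[i, j])
                a.extend([ra] * c)
                b.extend([cb] * c)
        return np.asarray(a), np.asarray(b)

    def squared(self) -> "ContingencyTable":
        """Zero-pad to a square table over the union of row/column labels."""
        labels = sorted(set(self.row_labels) | set(self.col_labels))
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        ri = {l: i for i, l in enumerate(labels)}
        for i, ra in enumerate(self.row_labels):
            for j, cb in enumerate(self.col_labels):
                counts[ri[ra], ri[cb]] = self.counts[i, j]
        return ContingencyTable(counts, tuple(labels), tuple(labels))


@dataclass(frozen=True)
class ConcordanceResult:
    """Bundle of the traditional metrics for one paired-grades table."""

    percent_agreement: float
    weighted_kappa: float
    kappa_scheme: str
    spearman_r: float
    diagonal_count: int
    n: int


def crosstab(
    pairs: Iterable[tuple[int, int]],
    row_labels: Sequence[int] | None = None,
    col_labels: Sequence[int] | None = None,
) -> ContingencyTable:
    """Tally (grade_a, grade_b) pairs into a contingency table.

    With explicit label sets, out-of-range grades are rejected; otherwise
    labels are the observed values (empty input needs explicit labels).
    """
    pairs = list(pairs)
    if not pairs and (row_labels is None or col_labels is None):
        raise ValueError("empty input requires explicit row/col labels")
    a = np.asarray([p[0] for p in pairs], dtype=np.int64)
    b = np.asarray([p[1] for p in pairs], dtype=np.int64)
    rl = tuple(sorted(set(a.tolist()))) if row_labels is None else tuple(row_labels)
    cl = tuple(sorted(set(b.tolist()))) if col_labels is None else tuple(col_labels)
    if pairs:
        if not set(a.tolist()) <= set(rl):
            bad = sorted(set(a.tolist()) - set(rl))[0]
            raise ValueError(f"grade {bad} outside declared row labels {rl}")
        if not set(b.tolist()) <= set(cl):
            bad = sorted(set(b.tolist()) - set(cl))[0]
            raise ValueError(f"grade {bad} outside declared column labels {cl}")
    counts = np.zeros((len(rl), len(cl)), dtype=np.int64)
    ri = {l: i for i, l in enumerate(rl)}
    ci = {l: i for i, l in enumerate(cl)}
    for x, y in zip(a, b):
        counts[ri[int(x)], ci[int(y)]] += 1
    return ContingencyTable(counts, rl, cl)


def diagonal_count(ct: ContingencyTable) -> int:
    """Number of pairs on the matched-label main diagonal."""
    total = 0
    ci = {l: j for j, l in enumerate(ct.col_labels)}
    for i, ra in enumerate(ct.row_labels):
        if ra in ci:
            total += int(ct.counts[i, ci[ra]])
    return total


def percent_agreement(ct: ContingencyTable) -> float:
    """Raw agreement: matched-label diagonal count over n."""
    if ct.n == 0:
        raise DegenerateTableError("empty table: agreement undefined")
    return diagonal_count(ct) / ct.n


def weighted_kappa(ct: ContingencyTable, scheme: str = "linear") -> float:
    """Cohen's weighted kappa with linear or quadratic disagreement weights.

    kappa_w = 1 - sum(w O) / sum(w E), with w_ij = |i-j| (linear) or
    (i-j)^2 (quadratic) over the squared table and E the product of the
    margins.  Rectangular input is zero-padded to a square over the union
    of labels.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"unknown weight scheme {scheme!r}")
    sq = ct.squared()
    if sq.n == 0:
        raise DegenerateTableError("empty table: kappa undefined")
    P = sq.counts / sq.n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    i, j = np.indices(P.shape)
    w = np.abs(i - j) if scheme == "linear" else (i - j) ** 2
    denom = (w * E).sum()
    if denom == 0:
        raise DegenerateTableError(
            "degenerate marginals (all mass in one category): kappa undefined")
    return float(1.0 - (w * P).sum() / denom)


def _midranks(margin: np.ndarray) -> np.ndarray:
    """Midrank of each category given its marginal counts."""
    cum = np.concatenate(([0], np.cumsum(margin)))
    return cum[:-1] + (margin + 1) / 2.0


def spearman_from_table(ct: ContingencyTable) -> float:
    """Spearman rank correlation with midranks for ties, from the margins.

    Equals the Pearson correlation of the midrank-transformed expanded pair
    vectors, computed without expansion.
    """
    if ct.n < 2:
        raise DegenerateTableError("need n >= 2 for a correlation")
    rm = ct.counts.sum(axis=1)
    cm = ct.counts.sum(axis=0)
    if (rm > 0).sum() < 2 or (cm > 0).sum() < 2:
        raise DegenerateTableError("constant margin: correlation undefined")
    ra = _midranks(rm)
    rb = _midranks(cm)
    n = ct.n
    mean_rank = (n + 1) / 2.0
    da = ra - mean_rank
    db = rb - mean_rank
    cov = float((ct.counts * np.outer(da, db)).sum())
    var_a = float((rm * da ** 2).sum())
    var_b = float((cm * db ** 2).sum())
    return cov / np.sqrt(var_a * var_b)


def concordance_metrics(ct: ContingencyTable, scheme: str = "linear") -> ConcordanceResult:
    """All traditional metrics for one table, with the kappa scheme tagged."""
    return ConcordanceResult(
        percent_agreement=percent_agreement(ct),
        weighted_kappa=weighted_kappa(ct, scheme),
        kappa_scheme=scheme,
        spearman_r=spearman_from_table(ct),
        diagonal_count=diagonal_count(ct),
        n=ct.n,
    )


def conditional_grade_table(
    table: RatingsTable, attribute_values: Sequence[int],
    grades: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Clinician-grade counts among patients whose every attribute equals v.

    For each v in ``attribute_values``, selects the patients whose observed
    attribute responses are all exactly v (patients with any missing
    attribute are excluded) and tallies their clinician grades.  Returns a
    DataFrame indexed by v with one column per clinician grade.
    """
    attr_idx = [j for j, it in enumerate(table.items)
                if it.role == "patient_attribute"]
    block = table.responses[:, attr_idx]
    clin = table.clinician_grades().to_numpy()
    if grades is None:
        observed = clin[np.isfinite(clin)].astype(int)
        grades = sorted(set(observed.tolist())) if observed.size else [0]
    out = pd.DataFrame(0, index=list(attribute_values), columns=list(grades))
    out.index.name = "attribute_value"
    for v in attribute_values:
        sel = (block == v).all(axis=1) & np.isfinite(clin)
        vals, counts = np.unique(clin[sel].astype(int), return_counts=True)
        for g, c in zip(vals, counts):
            if g in out.columns:
                out.loc[v, g] = int(c)
    return out
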