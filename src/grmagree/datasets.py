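"""Reference tables transcribed from a published multicentre comparison of
clinician CTCAE grades and patient-reported (PRO-CTCAE) pain ratings.

These small printed tables let the concordance metrics be exercised against
known published values without access to the underlying patient-level data
(which was never deposited).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import ContingencyTable

# Cross-tabulation of patient-reported pain severity (rows, 0=none ..
# 4=very severe) against the clinician CTCAE pain grade (columns, 0..3),
# n=525 patients with both ratings captured.  Row totals 5/210/183/91/36,
# column totals 190/217/96/22, main diagonal 132.
_PAIN_CROSSTAB = np.array([
    [2, 2, 1, 0],
    [112, 85, 13, 0],
    [56, 92, 32, 3],
    [16, 33, 29, 13],
    [4, 5, 21, 6],
], dtype=np.int64)

# Clinician CTCAE pain grade counts (columns, grades 1..3) among the n=83
# patients who rated frequency, severity and interference all equal to the
# row value (1, 2 or 3).
_PAIN_CONDITIONAL = np.array([
    [21, 3, 0],
    [27, 8, 0],
    [9, 10, 5],
], dtype=np.int64)


def pain_severity_crosstab() -> ContingencyTable:
    """5x4 pain table: patient severity (0-4) x clinician grade (0-3), n=525."""
    return ContingencyTable(_PAIN_CROSSTAB.copy(), (0, 1, 2, 3, 4), (0, 1, 2, 3))


def pain_conditional_counts() -> pd.DataFrame:
    """Clinician grade distribution when all three pain attributes equal v.

    Rows are the common attribute value v = 1, 2, 3; columns are clinician
    grades 1..3; n=83.
    """
    out = pd.DataFrame(_PAIN_CONDITIONAL.copy(), index=[1, 2, 3],
                       columns=[1, 2, 3])
    out.index.name = "attribute_value"
    return out
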