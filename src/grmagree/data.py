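"""Ratings data model: raters-as-items layout, clinic clusters, skip coding, I/O.

A single adverse event (AE) is analysed at a time.  The wide layout has one
column ("item") per patient-reported attribute (frequency, severity,
interference, each on 0..K-1) and one column per clinic cluster; a patient's
single clinician grade sits in their own clinic's column and every other
clinic column is NOT_RATED for them.  Two distinct missing states are kept:

* ``NOT_RATED`` -- the rating was never collected (a clinic that did not see
  the patient, or an attribute absent from the instrument);
* ``SKIPPED`` -- survey branching suppressed the question because the first
  attribute was answered 0 (never / none).

The likelihood treats both as absent; the distinction is preserved for
reporting and round-tripping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: integer codes used in :attr:`RatingsTable.responses`
NOT_RATED: int = -1
SKIPPED: int = -2

ROLE_ATTRIBUTE = "patient_attribute"
ROLE_CLINIC = "clinic"


class RatingsError(ValueError):
    """Raised on malformed ratings input (schema, range or structure)."""


@dataclass(frozen=True)
class ItemInfo:
    """Descriptor of one rater-item (an attribute column or a clinic column)."""

    item_id: str
    n_categories: int = 5
    role: str = ROLE_ATTRIBUTE

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise RatingsError(
                f"item {self.item_id!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )
        if self.role not in (ROLE_ATTRIBUTE, ROLE_CLINIC):
            raise RatingsError(f"item {self.item_id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ClinicKey:
    """Composite clinic cluster: one observed (site, disease-group) pair.

    Individual clinician identities are typically unavailable, so the rater
    'item' on the clinician side is the site x cancer-type stratum in which
    the patient was graded.  ``clinic_index`` is 1-based, assigned in
    first-appearance order of the raw rows for determinism.
    """

    site_id: str
    disease_group: str
    clinic_index: int

    @property
    def label(self) -> str:
        return f"clinic{self.clinic_index}"


@dataclass
class RatingsTable:
    """Wide ratings matrix for one AE: patients x rater-items.

    ``responses[i, j]`` is the ordinal grade of patient ``patients[i]`` on
    item ``items[j]`` (0..K_j-1), or one of the negative missing codes
    ``NOT_RATED`` / ``SKIPPED``.
    """

    ae_name: str
    patients: list[str]
    items: list[ItemInfo]
    responses: np.ndarray
    clinic_keys: dict[str, ClinicKey] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int16)
        n, p = self.responses.shape
        if n != len(self.patients) or p != len(self.items):
            raise RatingsError(
                f"responses shape {self.responses.shape} does not match "
                f"{len(self.patients)} patients x {len(self.items)} items"
            )
        if len(set(self.patients)) != n:
            raise RatingsError("duplicate patient_id in table")
        for j, item in enumerate(self.items):
            col = self.responses[:, j]
            bad = (col >= item.n_categories) | ((col < 0) & ~np.isin(col, (NOT_RATED, SKIPPED)))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise RatingsError(
                    f"patient {self.patients[i]!r}, item {item.item_id!r}: "
                    f"response {int(col[i])} outside 0..{item.n_categories - 1}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_index(self, item_id: str) -> int:
        for j, item in enumerate(self.items):
            if item.item_id == item_id:
                return j
        raise RatingsError(f"unknown item {item_id!r}")

    def observed_mask(self) -> np.ndarray:
        """Boolean patients x items mask of non-missing responses."""
        return self.responses >= 0

    def attribute_items(self) -> list[ItemInfo]:
        return [it for it in self.items if it.role == ROLE_ATTRIBUTE]

    def clinic_items(self) -> list[ItemInfo]:
        return [it for it in self.items if it.role == ROLE_CLINIC]

    def to_frame(self, na_token: str = "N/A", skip_token: str = "--") -> pd.DataFrame:
        """Wide human-readable view (patients as rows, items as columns)."""
        out = pd.DataFrame(index=pd.Index(self.patients, name="patient_id"))
        for j, item in enumerate(self.items):
            col = self.responses[:, j]
            vals = [
                na_token if v == NOT_RATED else skip_token if v == SKIPPED else str(int(v))
                for v in col
            ]
            out[item.item_id] = vals
        return out

    def clinician_grades(self) -> pd.Series:
        """Each patient's single clinician grade (NaN where none recorded)."""
        clinic_cols = [j for j, it in enumerate(self.items) if it.role == ROLE_CLINIC]
        if not clinic_cols:
            return pd.Series(np.nan, index=self.patients, name="clinician_grade")
        block = self.responses[:, clinic_cols]
        obs = block >= 0
        grades = np.full(self.n_patients, np.nan)
        rows, cols = np.nonzero(obs)
        grades[rows] = block[rows, cols]
        return pd.Series(grades, index=self.patients, name="clinician_grade")

    def validate(self) -> None:
        """Enforce structural invariants beyond per-cell range checks."""
        clinic_cols = [j for j, it in enumerate(self.items) if it.role == ROLE_CLINIC]
        if clinic_cols:
            n_obs = (self.responses[:, clinic_cols] >= 0).sum(axis=1)
            if (n_obs > 1).any():
                i = int(np.flatnonzero(n_obs > 1)[0])
                raise RatingsError(
                    f"patient {self.patients[i]!r} has clinician grades from "
                    f"{int(n_obs[i])} clinics; expected at most one"
                )
        if not any(it.role == ROLE_ATTRIBUTE for it in self.items):
            raise RatingsError("table has no patient_attribute items")


# ---------------------------------------------------------------------------
# restructuring operations
# ---------------------------------------------------------------------------

def make_clinic_keys(
    raw_rows: Iterable[tuple[str, str, str]],
) -> dict[str, ClinicKey]:
    """Map each patient to their composite clinic cluster.

    Parameters
    ----------
    raw_rows
        Iterable of ``(patient_id, site_id, disease_group)``; every patient
        must appear exactly once.

    Returns
    -------
    dict
        ``patient_id -> ClinicKey``.  Distinct (site, disease) pairs receive
        contiguous 1-based indices in first-appearance order.
    """
    keys: dict[str, ClinicKey] = {}
    pair_index: dict[tuple[str, str], int] = {}
    for patient_id, site, disease in raw_rows:
        if patient_id in keys:
            raise RatingsError(f"duplicate patient_id {patient_id!r}")
        pair = (str(site), str(disease))
        if pair not in pair_index:
            pair_index[pair] = len(pair_index) + 1
        keys[patient_id] = ClinicKey(pair[0], pair[1], pair_index[pair])
    return keys


def apply_skip_coding(
    table: RatingsTable, attribute_order: Sequence[str]
) -> RatingsTable:
    """Recode survey-branching skips: first attribute 0 silences the rest.

    Whenever the first attribute in ``attribute_order`` is 0 for a patient,
    every later attribute in the list is set to ``SKIPPED`` for that patient.
    All other cells are unchanged.  Idempotent.
    """
    if not attribute_order:
        raise RatingsError("attribute_order is empty")
    idx = [table.item_index(a) for a in attribute_order]  # raises on unknown
    resp = table.responses.copy()
    fire = resp[:, idx[0]] == 0
    for j in idx[1:]:
        resp[fire, j] = SKIPPED
    return replace(table, responses=resp)


def restructure_to_items(
    patient_block: pd.DataFrame,
    clinician_block: Mapping[str, int] | pd.Series,
    clinic_keys: Mapping[str, ClinicKey],
    *,
    ae_name: str = "AE",
    n_categories: int = 5,
    clinic_categories: int | None = None,
) -> RatingsTable:
    """Build the raters-as-items wide table from patient and clinician blocks.

    Parameters
    ----------
    patient_block
        DataFrame indexed by patient_id with one column per attribute;
        values are grades 0..K-1, or negative missing codes / NaN.
    clinician_block
        patient_id -> single clinician grade (may omit patients).
    clinic_keys
        patient_id -> :class:`ClinicKey`; must cover every patient graded by
        a clinician.
    n_categories, clinic_categories
        Number of ordinal categories for attribute and clinic items
        (clinic defaults to ``n_categories``).

    Each graded patient's clinician grade is placed in their own clinic's
    item; every other clinic item is ``NOT_RATED`` for them.
    """
    if clinic_categories is None:
        clinic_categories = n_categories
    clin = pd.Series(clinician_block, dtype=float)

    missing = [p for p in clin.index if p not in clinic_keys]
    if missing:
        raise RatingsError(
            f"patient {missing[0]!r} has a clinician grade but no clinic key"
        )

    patients = [str(p) for p in patient_block.index]
    attr_items = [
        ItemInfo(str(c), n_categories, ROLE_ATTRIBUTE) for c in patient_block.columns
    ]
    n_clinics = max((k.clinic_index for k in clinic_keys.values()), default=0)
    clinic_items = [
        ItemInfo(f"clinic{i}", clinic_categories, ROLE_CLINIC)
        for i in range(1, n_clinics + 1)
    ]

    resp = np.full((len(patients), len(attr_items) + len(clinic_items)), NOT_RATED,
                   dtype=np.int16)
    attr_vals = patient_block.to_numpy(dtype=float)
    obs = np.isfinite(attr_vals) & (attr_vals >= 0)
    resp[:, : len(attr_items)][obs] = attr_vals[obs].astype(np.int16)
    skip = np.isfinite(attr_vals) & (attr_vals == SKIPPED)
    resp[:, : len(attr_items)][skip] = SKIPPED

    pat_pos = {p: i for i, p in enumerate(patients)}
    for pid, grade in clin.items():
        if not np.isfinite(grade):
            continue
        pid = str(pid)
        if pid not in pat_pos:
            raise RatingsError(
                f"patient {pid!r} in clinician block absent from patient block"
            )
        col = len(attr_items) + clinic_keys[pid].clinic_index - 1
        resp[pat_pos[pid], col] = int(grade)

    table = RatingsTable(
        ae_name=ae_name,
        patients=patients,
        items=attr_items + clinic_items,
        responses=resp,
        clinic_keys={str(k): v for k, v in clinic_keys.items()},
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# delimited-file I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingsSchema:
    """Column layout of the raw long/flat delimited file (one row per patient)."""

    attribute_cols: tuple[str, ...] = ("frequency", "severity", "interference")
    patient_col: str = "patient_id"
    site_col: str = "site"
    disease_col: str = "disease"
    clinician_col: str = "clinician_grade"
    missing_token: str = "NA"
    skipped_token: str = "--"
    delimiter: str = ","
    n_categories: int = 5
    clinic_categories: int = 5
    ae_name: str = "AE"


def read_ratings(path, schema: RatingsSchema = RatingsSchema()) -> RatingsTable:
    """Read a raw per-patient delimited file into a restructured RatingsTable.

    The file must have a header row with the schema's declared columns; the
    clinician column is optional (patient-attributes-only table).  Cells equal
    to the missing token become ``NOT_RATED``; the skipped token becomes
    ``SKIPPED``.  Malformed cells are rejected with their row number.
    """
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str,
                     keep_default_na=False)
    required = [schema.patient_col, schema.site_col, schema.disease_col,
                *schema.attribute_cols]
    for col in required:
        if col not in df.columns:
            raise RatingsError(f"missing required column {col!r}")
    known = set(required) | {schema.clinician_col}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise RatingsError(f"unknown column {unknown[0]!r}")

    def parse(cell: str, row: int, col: str, k: int) -> float:
        cell = cell.strip()
        if cell == schema.missing_token or cell == "":
            return float(NOT_RATED)
        if cell == schema.skipped_token:
            return float(SKIPPED)
        try:
            v = int(cell)
        except ValueError:
            raise RatingsError(f"row {row}: malformed value {cell!r} in {col!r}") from None
        if not 0 <= v < k:
            raise RatingsError(
                f"row {row}: grade {v} in {col!r} outside 0..{k - 1}"
            )
        return float(v)

    patients = df[schema.patient_col].astype(str).tolist()
    if len(set(patients)) != len(patients):
        dup = pd.Series(patients)[pd.Series(patients).duplicated()].iloc[0]
        raise RatingsError(f"duplicate patient_id {dup!r}")

    attr = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    for col in schema.attribute_cols:
        attr[col] = [
            parse(c, i + 2, col, schema.n_categories)
            for i, c in enumerate(df[col])
        ]
    attr = attr.where(attr != NOT_RATED, np.nan)

    clin: pd.Series
    if schema.clinician_col in df.columns:
        vals = [
            parse(c, i + 2, schema.clinician_col, schema.clinic_categories)
            for i, c in enumerate(df[schema.clinician_col])
        ]
        clin = pd.Series(vals, index=patients)
        clin = clin.where(clin >= 0, np.nan)
    else:
        clin = pd.Series(np.nan, index=patients)

    keys = make_clinic_keys(
        zip(patients, df[schema.site_col].astype(str), df[schema.disease_col].astype(str))
    )
    return restructure_to_items(
        attr, clin, keys, ae_name=schema.ae_name,
        n_categories=schema.n_categories,
        clinic_categories=schema.clinic_categories,
    )


def write_ratings(table: RatingsTable, path,
                  schema: RatingsSchema = RatingsSchema()) -> None:
    """Write a RatingsTable back to the raw per-patient delimited layout.

    Requires ``table.clinic_keys`` (to recover site/disease columns).
    ``read_ratings(write_ratings(t)) == t`` on the data model.
    """
    if table.clinic_keys is None:
        raise RatingsError("table has no clinic_keys; cannot recover site/disease")
    attr_items = table.attribute_items()
    grades = table.clinician_grades()

    def fmt(code: int) -> str:
        if code == NOT_RATED:
            return schema.missing_token
        if code == SKIPPED:
            return schema.skipped_token
        return str(int(code))

    rows = []
    for i, pid in enumerate(table.patients):
        key = table.clinic_keys.get(pid)
        if key is None:
            raise RatingsError(f"patient {pid!r} missing from clinic_keys")
        row = {
            schema.patient_col: pid,
            schema.site_col: key.site_id,
            schema.disease_col: key.disease_group,
        }
        for item in attr_items:
            row[item.item_id] = fmt(int(table.responses[i, table.item_index(item.item_id)]))
        g = grades.iloc[i]
        row[schema.clinician_col] = schema.missing_token if not np.isfinite(g) else str(int(g))
        rows.append(row)
    out = pd.DataFrame(rows)
    if isinstance(path, io.IOBase):
        out.to_csv(path, sep=schema.delimiter, index=False)
    else:
        out.to_csv(path, sep=schema.delimiter, index=False)
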