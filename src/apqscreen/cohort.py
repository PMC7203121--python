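"""Questionnaire-cohort data model and file I/O.

A cohort is a table of binary (yes/no, possibly missing) questionnaire
responses for children presenting with acute respiratory symptoms, together
with a gold-standard "asthma syndrome" label per child (expert-panel
diagnosis of asthma, bronchiolitis, or combined asthma and bacterial
pneumonia), the child's age in months, and optionally the detailed panel
diagnosis.  Every downstream stage — single-item diagnostic properties,
lookup-table screening rules, exhaustive combination search — consumes this
container.

Answer patterns over a small item subset are summarised by a
:class:`PatternTable`: for each of the 2^k yes/no patterns, the number of
children showing it and the percentage split between children with and
without asthma syndrome.  Pattern tables are both an output (the printed
form of a fitted screening rule) and an input (published tables can be
re-expanded into integer counts and audited).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemCodebook",
    "Cohort",
    "PatternTable",
    "SchemaError",
    "CohortValidationError",
    "load_cohort",
    "save_cohort",
    "reconstruct_pattern_counts",
    "pattern_table_from_cohort",
    "cohort_from_pattern_table",
    "round_half_away",
]

#: Detailed diagnoses that constitute the composite positive label.
ASTHMA_SYNDROME_DETAILS = frozenset(
    {"bronchiolitis", "asthma", "combined asthma and bacterial pneumonia"}
)
#: Detailed diagnoses for label-negative children.
NON_SYNDROME_DETAILS = frozenset({"bacterial pneumonia", "viral pneumonia", "other"})

AGE_MIN_MONTHS = 2
AGE_MAX_MONTHS = 59


class SchemaError(ValueError):
    """A cohort file does not have the expected columns."""


class CohortValidationError(ValueError):
    """Cohort contents violate a structural invariant."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used wherever printed percentages are converted back to integer counts,
    because banker's rounding would not reproduce published totals.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ItemCodebook:
    """Codebook mapping item identifiers to question wordings.

    Parameters
    ----------
    item_ids
        Short stable identifiers, one per response-matrix column.
    wordings
        Free-text question wordings, parallel to ``item_ids``.
    sections
        Free-text grouping of each item (e.g. ``"disease today"``,
        ``"earlier problems (since birth)"``).
    """

    item_ids: tuple[str, ...]
    wordings: tuple[str, ...] = ()
    sections: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = self.item_ids
        if len(ids) != len(set(ids)):
            raise CohortValidationError("item_ids must be unique")
        if any(not i for i in ids):
            raise CohortValidationError("item_ids must be non-empty strings")
        for name in ("wordings", "sections"):
            vals = getattr(self, name)
            if vals and len(vals) != len(ids):
                raise CohortValidationError(f"{name} length must match item_ids")

    def __len__(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.item_ids)
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "wording": self.wordings or [""] * n,
                "section": self.sections or [""] * n,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemCodebook":
        missing = {"item_id"} - set(df.columns)
        if missing:
            raise SchemaError("codebook is missing required column 'item_id'")
        return cls(
            item_ids=tuple(df["item_id"].astype(str)),
            wordings=tuple(df["wording"].fillna("").astype(str))
            if "wording" in df
            else (),
            sections=tuple(df["section"].fillna("").astype(str))
            if "section" in df
            else (),
        )


@dataclass
class Cohort:
    """A questionnaire cohort: responses, gold labels and ages.

    Attributes
    ----------
    responses
        Children x items matrix; ``1.0`` yes, ``0.0`` no, ``NaN`` missing.
    item_ids
        Column identifiers, same order as the response columns.
    gold_label
        Boolean per child; ``True`` = asthma syndrome.
    age_months
        Integer age in months per child, within [2, 59].
    diagnosis_detail
        Optional detailed expert-panel diagnosis per child.  Carried for
        reporting only, never used by any classifier.
    child_id
        Optional identifiers; carried but never used analytically.
    """

    responses: np.ndarray
    item_ids: tuple[str, ...]
    gold_label: np.ndarray
    age_months: np.ndarray
    diagnosis_detail: np.ndarray | None = None
    child_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise CohortValidationError("responses must be a 2-D matrix")
        self.item_ids = tuple(self.item_ids)
        self.gold_label = np.asarray(self.gold_label, dtype=bool)
        self.age_months = np.asarray(self.age_months, dtype=int)
        n, m = self.responses.shape
        if len(self.item_ids) != m:
            raise CohortValidationError(
                f"{len(self.item_ids)} item_ids for {m} response columns"
            )
        if len(set(self.item_ids)) != m:
            raise CohortValidationError("item_ids must be unique")
        if len(self.gold_label) != n or len(self.age_months) != n:
            raise CohortValidationError(
                "gold_label and age_months must have one entry per child"
            )
        bad = np.flatnonzero(
            (self.age_months < AGE_MIN_MONTHS) | (self.age_months > AGE_MAX_MONTHS)
        )
        if bad.size:
            raise CohortValidationError(
                f"age_months outside [{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}] "
                f"at row index {bad[0]} (value {self.age_months[bad[0]]})"
            )
        vals = self.responses[~np.isnan(self.responses)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise CohortValidationError("responses must be 0, 1 or missing")
        if self.diagnosis_detail is not None:
            self.diagnosis_detail = np.asarray(self.diagnosis_detail, dtype=object)
            if len(self.diagnosis_detail) != n:
                raise CohortValidationError("diagnosis_detail length mismatch")
            is_syndrome = np.array(
                [d in ASTHMA_SYNDROME_DETAILS for d in self.diagnosis_detail]
            )
            if not np.array_equal(is_syndrome, self.gold_label):
                raise CohortValidationError(
                    "gold_label must be positive iff diagnosis_detail is "
                    "asthma, bronchiolitis or combined asthma and bacterial pneumonia"
                )
        if self.child_id is not None:
            self.child_id = np.asarray(self.child_id, dtype=object)
            if len(self.child_id) != n:
                raise CohortValidationError("child_id length mismatch")

    @property
    def n_children(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def prevalence(self) -> float:
        """Fraction of children with the asthma-syndrome label."""
        return float(self.gold_label.mean()) if self.n_children else float("nan")

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    def columns(self, items: Sequence[str]) -> np.ndarray:
        """Response sub-matrix for the given items, in the given order."""
        idx = [self.item_index(i) for i in items]
        return self.responses[:, idx]

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Cohort restricted to the children selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            responses=self.responses[mask],
            item_ids=self.item_ids,
            gold_label=self.gold_label[mask],
            age_months=self.age_months[mask],
            diagnosis_detail=None
            if self.diagnosis_detail is None
            else self.diagnosis_detail[mask],
            child_id=None if self.child_id is None else self.child_id[mask],
        )


# ---------------------------------------------------------------------------
# File I/O: comma-separated UTF-8 with a header row; responses coded
# yes/no with missing as empty cell or "NA".
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("child_id", "age_months")
_YES = {"yes", "1", "1.0", "true"}
_NO = {"no", "0", "0.0", "false"}
_MISSING = {"", "na", "nan", "none"}


def _decode_response(value: object, column: str, row: int) -> float:
    s = str(value).strip().lower()
    if s in _YES:
        return 1.0
    if s in _NO:
        return 0.0
    if s in _MISSING:
        return float("nan")
    raise CohortValidationError(
        f"uninterpretable response {value!r} in column {column!r}, row {row}"
    )


def _decode_label(value: object, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _YES:
        return True
    if s in _NO:
        return False
    raise CohortValidationError(f"gold_label not binary-codable at row {row}: {value!r}")


def load_cohort(path: str | Path, codebook_path: str | Path | None = None,
                codebook: ItemCodebook | None = None) -> Cohort:
    """Load a cohort from a delimited file, validating against a codebook.

    The file must have one header row with columns ``child_id``,
    ``age_months``, ``gold_label`` and/or ``diagnosis_detail``, then one
    column per codebook item with values in {yes, no, 1, 0, NA}.  Unknown
    columns are rejected.
    """
    if codebook is None:
        if codebook_path is None:
            raise ValueError("either codebook_path or codebook is required")
        codebook = ItemCodebook.from_frame(pd.read_csv(codebook_path, dtype=str))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    meta = [c for c in cols if c in ("child_id", "age_months", "gold_label",
                                     "diagnosis_detail")]
    for required in _REQUIRED_COLUMNS:
        if required not in cols:
            raise SchemaError(f"missing required column {required!r}")
    if "gold_label" not in cols and "diagnosis_detail" not in cols:
        raise SchemaError("missing required column 'gold_label' (or 'diagnosis_detail')")
    item_cols = [c for c in cols if c not in meta]
    unknown = [c for c in item_cols if c not in codebook.item_ids]
    if unknown:
        raise SchemaError(f"unknown columns not in codebook: {unknown}")
    absent = [c for c in codebook.item_ids if c not in item_cols]
    if absent:
        raise SchemaError(f"missing codebook item columns: {absent}")

    n = len(df)
    detail = None
    if "diagnosis_detail" in cols:
        detail = df["diagnosis_detail"].astype(object).to_numpy()
        gold = np.array([d in ASTHMA_SYNDROME_DETAILS for d in detail])
        if "gold_label" in cols:
            explicit = np.array(
                [_decode_label(v, i) for i, v in enumerate(df["gold_label"])]
            )
            if not np.array_equal(explicit, gold):
                raise CohortValidationError(
                    "gold_label inconsistent with diagnosis_detail"
                )
    else:
        gold = np.array([_decode_label(v, i) for i, v in enumerate(df["gold_label"])])

    try:
        ages = df["age_months"].astype(int).to_numpy()
    except ValueError as exc:
        raise CohortValidationError(f"non-integer age_months: {exc}") from exc

    responses = np.empty((n, len(codebook.item_ids)))
    for j, item in enumerate(codebook.item_ids):
        col = df[item]
        responses[:, j] = [_decode_response(v, item, i) for i, v in enumerate(col)]

    return Cohort(
        responses=responses,
        item_ids=codebook.item_ids,
        gold_label=gold,
        age_months=ages,
        diagnosis_detail=detail,
        child_id=df["child_id"].to_numpy(dtype=object),
    )


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; ``load_cohort`` on the result is the identity.

    Output is byte-stable for a fixed cohort: columns and rows keep their
    in-memory order and values are written as yes/no/NA.
    """
    n = cohort.n_children
    child_id = (
        cohort.child_id
        if cohort.child_id is not None
        else np.array([f"c{i:05d}" for i in range(n)], dtype=object)
    )
    data: dict[str, object] = {
        "child_id": child_id,
        "age_months": cohort.age_months,
        "gold_label": np.where(cohort.gold_label, "yes", "no"),
    }
    if cohort.diagnosis_detail is not None:
        data["diagnosis_detail"] = cohort.diagnosis_detail
    for j, item in enumerate(cohort.item_ids):
        col = cohort.responses[:, j]
        data[item] = np.where(
            np.isnan(col), "NA", np.where(col == 1.0, "yes", "no")
        )
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pattern tables
# ---------------------------------------------------------------------------

LABEL_POSITIVE = "asthma"
LABEL_NEGATIVE = "no asthma"
LABEL_UNDEFINED = "undefined"

#: Tolerance on pct_without + pct_with - 100 for rows printed to one decimal.
_PCT_SUM_TOL = 0.2


@dataclass
class PatternRow:
    """One answer pattern of a :class:`PatternTable`."""

    pattern: tuple[bool, ...]
    n: int
    pct_without: float
    pct_with: float
    indicated: str = LABEL_UNDEFINED


@dataclass
class PatternTable:
    """Per-pattern counts and class percentages over an ordered item subset.

    Rows cover all ``2^k`` yes/no patterns of the ``k`` items, each with the
    number of children showing the pattern, the percentage split between
    children without and with asthma syndrome, and optionally the label a
    majority-rule screening rule indicates for the pattern.
    """

    items: tuple[str, ...]
    rows: list[PatternRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        k = len(self.items)
        if len(self.rows) != 2 ** k:
            raise CohortValidationError(
                f"expected {2 ** k} rows for {k} items, got {len(self.rows)}"
            )
        seen = set()
        for row in self.rows:
            if len(row.pattern) != k:
                raise CohortValidationError("pattern length must equal item count")
            if row.pattern in seen:
                raise CohortValidationError(f"duplicate pattern {row.pattern}")
            seen.add(row.pattern)
            if row.n < 0:
                raise CohortValidationError("pattern count n must be nonnegative")
            for pct in (row.pct_without, row.pct_with):
                if not 0.0 <= pct <= 100.0:
                    raise CohortValidationError("percentages must lie in [0, 100]")
            if row.n > 0 and abs(row.pct_without + row.pct_with - 100.0) > _PCT_SUM_TOL:
                raise CohortValidationError(
                    f"percentages for pattern {row.pattern} do not sum to 100"
                )

    @property
    def n_total(self) -> int:
        return sum(row.n for row in self.rows)

    def row(self, pattern: Sequence[bool]) -> PatternRow:
        target = tuple(bool(p) for p in pattern)
        for row in self.rows:
            if row.pattern == target:
                return row
        raise KeyError(f"no row for pattern {target}")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {item: ("yes" if v else "no") for item, v in zip(self.items, row.pattern)}
            rec.update(
                n=row.n,
                pct_without=row.pct_without,
                pct_with=row.pct_with,
                indicated=row.indicated,
            )
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PatternTable":
        meta = {"n", "pct_without", "pct_with", "indicated"}
        items = tuple(c for c in df.columns if c not in meta)
        rows = [
            PatternRow(
                pattern=tuple(str(rec[i]).strip().lower() in _YES for i in items),
                n=int(rec["n"]),
                pct_without=float(rec["pct_without"]),
                pct_with=float(rec["pct_with"]),
                indicated=str(rec.get("indicated", LABEL_UNDEFINED)),
            )
            for rec in df.to_dict("records")
        ]
        return cls(items=items, rows=rows)


def reconstruct_pattern_counts(table: PatternTable) -> pd.DataFrame:
    """Convert a pattern table's printed percentages back to integer counts.

    For each row, ``count_with = round_half_away(n * pct_with / 100)`` and
    ``count_without = n - count_with``.  With percentages printed to one
    decimal this recovers the underlying integer counts exactly for all n
    below 250.

    Returns a DataFrame with one row per pattern and columns
    ``count_with`` and ``count_without``, indexed like ``table.rows``.
    """
    recs = []
    for row in table.rows:
        count_with = round_half_away(row.n * row.pct_with / 100.0)
        count_without = row.n - count_with
        if count_without < 0:
            raise CohortValidationError(
                f"inconsistent row {row.pattern}: count_with exceeds n"
            )
        recs.append(
            {
                "pattern": row.pattern,
                "n": row.n,
                "count_with": count_with,
                "count_without": count_without,
                "indicated": row.indicated,
            }
        )
    return pd.DataFrame(recs)


def pattern_table_from_cohort(
    cohort: Cohort,
    items: Sequence[str],
    indicated: dict[tuple[bool, ...], str] | None = None,
    missing_policy: str = "impute_no",
) -> PatternTable:
    """Tabulate a cohort over the answer patterns of an item subset.

    Percentages are computed from unrounded proportions, so
    :func:`reconstruct_pattern_counts` on the result returns the exact
    original counts.
    """
    from .screener import encode_patterns  # local import to avoid a cycle

    codes = encode_patterns(cohort, items, missing_policy=missing_policy)
    k = len(items)
    gold = cohort.gold_label
    rows = []
    for code in range(2 ** k):
        pattern = tuple(bool((code >> t) & 1) for t in range(k))
        in_pattern = codes == code
        n = int(in_pattern.sum())
        n_with = int((in_pattern & gold).sum())
        if n:
            pct_with = 100.0 * n_with / n
            pct_without = 100.0 * (n - n_with) / n
        else:
            pct_with = pct_without = 0.0
        rows.append(
            PatternRow(
                pattern=pattern,
                n=n,
                pct_without=pct_without,
                pct_with=pct_with,
                indicated=(indicated or {}).get(pattern, LABEL_UNDEFINED),
            )
        )
    return PatternTable(items=tuple(items), rows=rows)


def cohort_from_pattern_table(table: PatternTable, age_months: int = 12) -> Cohort:
    """Expand a pattern table into an explicit cohort of children.

    Each pattern contributes ``count_with`` label-positive and
    ``count_without`` label-negative children whose responses over the
    table's items equal the pattern.  Ages are filled with a constant
    (the table carries no age information).  This is the bridge from a
    published pattern table back to a cohort every analysis stage accepts.
    """
    counts = reconstruct_pattern_counts(table)
    resp_rows: list[tuple[float, ...]] = []
    labels: list[bool] = []
    for rec in counts.itertuples():
        pattern = tuple(float(v) for v in rec.pattern)
        resp_rows.extend([pattern] * rec.count_with)
        labels.extend([True] * rec.count_with)
        resp_rows.extend([pattern] * rec.count_without)
        labels.extend([False] * rec.count_without)
    responses = (
        np.array(resp_rows, dtype=float)
        if resp_rows
        else np.empty((0, len(table.items)))
    )
    return Cohort(
        responses=responses,
        item_ids=table.items,
        gold_label=np.array(labels, dtype=bool),
        age_months=np.full(len(labels), age_months, dtype=int),
    )
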