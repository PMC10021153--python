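"""Disease codebook and person-level cohort container.

The analysis operates on a fixed codebook of 16 self-reported chronic
non-communicable diseases, each coded as a binary indicator (0 = absent,
1 = present).  The codebook order is alphabetical by abbreviation and is
the canonical row/column order for every matrix and network produced
downstream.

A :class:`Cohort` wraps a pandas DataFrame with one row per respondent:
an opaque person id, a two-level gender stratum (``women``/``men``), age
in years, a positive sampling weight, and the 16 indicator columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseCode",
    "DEFAULT_CODEBOOK",
    "CODES",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "disease_count",
    "filter_multimorbid",
    "split_by_gender",
]

GENDERS = ("women", "men")

ID_COLUMNS = ("person_id", "gender", "age", "weight")


class SchemaError(ValueError):
    """A cohort file does not have the expected columns."""


class ValidationError(ValueError):
    """A cohort row violates the data contract (bad indicator, gender, ...)."""


@dataclass(frozen=True)
class DiseaseCode:
    """One disease of the codebook: short abbreviation plus full label."""

    code: str
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


#: Canonical 16-disease codebook, alphabetical by abbreviation.  The order
#: fixes the axis order of dyad matrices, association lists and networks.
DEFAULT_CODEBOOK: tuple[DiseaseCode, ...] = (
    DiseaseCode("AS", "asthma"),
    DiseaseCode("CA", "cancer"),
    DiseaseCode("CB", "chronic bronchitis"),
    DiseaseCode("CHD", "chronic heart disease"),
    DiseaseCode("COPD", "chronic obstructive pulmonary disease"),
    DiseaseCode("CRF", "chronic renal failure"),
    DiseaseCode("DM", "diabetes mellitus"),
    DiseaseCode("GD", "gastrointestinal disorder"),
    DiseaseCode("HC", "high cholesterol"),
    DiseaseCode("HYP", "hypertension"),
    DiseaseCode("MKS", "musculoskeletal disorder"),
    DiseaseCode("NPD", "neurological and psychiatric disorder"),
    DiseaseCode("SD", "skin disease"),
    DiseaseCode("ST", "stroke"),
    DiseaseCode("THY", "thyroid disease"),
    DiseaseCode("UI", "urinary incontinence"),
)

#: Abbreviations of the default codebook, in canonical order.
CODES: tuple[str, ...] = tuple(d.code for d in DEFAULT_CODEBOOK)


def _codes(codebook: Sequence[DiseaseCode]) -> list[str]:
    return [d.code for d in codebook]


@dataclass
class Cohort:
    """Person-level cohort: records table + codebook + selection state.

    ``selection`` is ``"all"`` for an unselected cohort and
    ``"multimorbid"`` once the two-or-more-diseases filter has been
    applied; the multimorbid invariant (indicator row sums >= 2) is
    checked on construction.
    """

    df: pd.DataFrame
    codebook: tuple[DiseaseCode, ...] = DEFAULT_CODEBOOK
    selection: str = "all"

    def __post_init__(self) -> None:
        self.codebook = tuple(self.codebook)
        validate_cohort_frame(self.df, self.codebook)
        if self.selection not in ("all", "multimorbid"):
            raise ValidationError(f"unknown selection state {self.selection!r}")
        if self.selection == "multimorbid":
            counts = self.disease_counts()
            if (counts < 2).any():
                raise ValidationError(
                    "multimorbid cohort contains records with fewer than 2 diseases"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def codes(self) -> list[str]:
        return _codes(self.codebook)

    @property
    def n(self) -> int:
        return len(self.df)

    def indicators(self) -> np.ndarray:
        """n x 16 integer matrix of disease indicators, codebook order."""
        return self.df[self.codes].to_numpy(dtype=np.int8)

    @property
    def age(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def weight(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    def disease_counts(self) -> np.ndarray:
        """Per-record number of diseases present (row sums, in [0, 16])."""
        return self.indicators().sum(axis=1)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.codebook, self.selection)


def validate_cohort_frame(df: pd.DataFrame, codebook: Sequence[DiseaseCode]) -> None:
    """Check the cohort data contract, raising on first violation.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (with the offending row position) for
    non-binary indicators, unknown gender tokens, non-positive weights,
    negative ages or missing cells.  Rows are never silently dropped.
    """
    codes = _codes(codebook)
    for col in (*ID_COLUMNS, *codes):
        if col not in df.columns:
            raise SchemaError(f"cohort is missing required column {col!r}")

    def _bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = np.flatnonzero(mask.to_numpy())
            raise ValidationError(f"{what} at row(s) {rows[:10].tolist()}")

    _bad_rows(~df["gender"].isin(GENDERS), "unknown gender token")
    age = pd.to_numeric(df["age"], errors="coerce")
    _bad_rows(age.isna() | (age < 0), "missing or negative age")
    weight = pd.to_numeric(df["weight"], errors="coerce")
    _bad_rows(weight.isna() | (weight <= 0), "missing or non-positive weight")
    for code in codes:
        vals = pd.to_numeric(df[code], errors="coerce")
        _bad_rows(~vals.isin([0, 1]), f"non-binary indicator {code!r}")


def read_cohort(path, codebook: Sequence[DiseaseCode] = DEFAULT_CODEBOOK) -> Cohort:
    """Read a cohort CSV (header mandatory, UTF-8) into a :class:`Cohort`.

    Expected columns: ``person_id,gender,age,weight`` followed by the 16
    disease abbreviations.  Malformed rows raise, they are never dropped.
    The returned cohort has ``selection="all"``.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "gender": str})
    validate_cohort_frame(df, codebook)
    codes = _codes(codebook)
    df = df[[*ID_COLUMNS, *codes]].copy()
    df["age"] = df["age"].astype(float)
    df["weight"] = df["weight"].astype(float)
    df[codes] = df[codes].astype(np.int8)
    return Cohort(df.reset_index(drop=True), tuple(codebook), "all")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV in the canonical column order."""
    cols = [*ID_COLUMNS, *cohort.codes]
    cohort.df[cols].to_csv(path, index=False)


def disease_count(record: pd.Series | Iterable, codebook: Sequence[DiseaseCode] = DEFAULT_CODEBOOK) -> int:
    """Number of diseases present for one record (sum of the indicators)."""
    if isinstance(record, pd.Series):
        values = record[_codes(codebook)].to_numpy()
    else:
        values = np.asarray(list(record))
    if not np.isin(values, [0, 1]).all():
        raise ValidationError("indicators must be exactly 0 or 1")
    return int(values.sum())


def filter_multimorbid(cohort: Cohort) -> Cohort:
    """Select records with two or more diseases (the multimorbid subset).

    The input cohort is unmodified; the result carries
    ``selection="multimorbid"``.  Idempotent by construction.
    """
    keep = cohort.disease_counts() >= 2
    return Cohort(cohort.df.loc[keep].reset_index(drop=True), cohort.codebook, "multimorbid")


def split_by_gender(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition a cohort into its (women, men) strata.

    The two strata are analysed separately throughout; records are never
    pooled across gender.  Unknown gender tokens raise.
    """
    bad = ~cohort.df["gender"].isin(GENDERS)
    if bad.any():
        raise ValidationError(f"unknown gender token at row(s) {np.flatnonzero(bad)[:10].tolist()}")
    women = cohort.df[cohort.df["gender"] == "women"].reset_index(drop=True)
    men = cohort.df[cohort.df["gender"] == "men"].reset_index(drop=True)
    return (
        Cohort(women, cohort.codebook, cohort.selection),
        Cohort(men, cohort.codebook, cohort.selection),
    )
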