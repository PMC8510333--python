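"""Hospitalization-level cohort container, validation, and CSV I/O.

The analysis unit throughout the package is the *hospitalization* (admission):
one row per admission carrying a binary end-of-life (EOL) indicator (death
within one year of admission), a binary usual-care code-status-order (CSO)
indicator, one predicted risk in [0, 1] per prediction model, and optional
categorical subgroup labels (e.g. hospital site, service type).

A patient may own several admissions; per-patient subsampling is the job of
:mod:`alertvalue.resampling`, not of this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RISK_PREFIX = "risk_"
SUBGROUP_PREFIX = "g_"
ORDER_KEY = "admission_seq"
REQUIRED_COLUMNS = ("patient_id", "admission_id", "eol", "cso")


class CohortError(ValueError):
    """Base class for cohort construction and I/O failures."""


class SchemaError(CohortError):
    """A required column is missing or mis-declared."""


class IntegrityError(CohortError):
    """Structural constraint violated (e.g. duplicate admission identifiers)."""


class CohortValidationError(CohortError):
    """A value-level constraint violated (risk out of range, non-binary flag)."""


class EmptyCohortError(CohortError):
    """An operation that needs at least one record received none."""


def _validate_frame(df: pd.DataFrame, model_names: Sequence[str],
                    subgroup_dimensions: Sequence[str]) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for m in model_names:
        if RISK_PREFIX + m not in df.columns:
            raise SchemaError(f"missing risk column {RISK_PREFIX + m!r}")
    for d in subgroup_dimensions:
        if SUBGROUP_PREFIX + d not in df.columns:
            raise SchemaError(f"missing subgroup column {SUBGROUP_PREFIX + d!r}")
    if df["admission_id"].duplicated().any():
        dup = df["admission_id"][df["admission_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate admission_id {dup!r}")
    for flag in ("eol", "cso"):
        vals = pd.unique(df[flag])
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            row = int(np.flatnonzero(~df[flag].isin((0, 1)).to_numpy())[0])
            raise CohortValidationError(
                f"{flag} must be binary 0/1; found {bad[0]!r} in row {row}")
    for m in model_names:
        r = df[RISK_PREFIX + m].to_numpy(dtype=float)
        out = ~((r >= 0.0) & (r <= 1.0))  # catches NaN too
        if out.any():
            row = int(np.flatnonzero(out)[0])
            raise CohortValidationError(
                f"risk {RISK_PREFIX + m!r} outside [0, 1] in row {row}: {r[row]!r}")


@dataclass
class Cohort:
    """A validated table of hospitalizations.

    Parameters
    ----------
    df :
        Frame with columns ``patient_id``, ``admission_id``, ``eol``, ``cso``,
        one ``risk_<model>`` column per model, optional ``g_<dimension>``
        subgroup columns and an optional ``admission_seq`` ordering key.
    model_names :
        Ordered risk-column names (without the ``risk_`` prefix).
    subgroup_dimensions :
        Subgroup dimension names (without the ``g_`` prefix).
    """

    df: pd.DataFrame
    model_names: tuple[str, ...] = ()
    subgroup_dimensions: tuple[str, ...] = ()
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.model_names = tuple(self.model_names)
        self.subgroup_dimensions = tuple(self.subgroup_dimensions)
        if self.validate:
            _validate_frame(self.df, self.model_names, self.subgroup_dimensions)

    # ---- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def eol(self) -> np.ndarray:
        return self.df["eol"].to_numpy(dtype=np.int64)

    @property
    def cso(self) -> np.ndarray:
        return self.df["cso"].to_numpy(dtype=np.int64)

    @property
    def n_eol(self) -> int:
        return int(self.eol.sum())

    @property
    def n_cso(self) -> int:
        return int(self.cso.sum())

    def risks(self, model_name: str) -> np.ndarray:
        col = RISK_PREFIX + model_name
        if col not in self.df.columns:
            raise KeyError(f"unknown model {model_name!r}")
        return self.df[col].to_numpy(dtype=float)

    def subgroup(self, dimension: str) -> np.ndarray:
        col = SUBGROUP_PREFIX + dimension
        if col not in self.df.columns:
            raise KeyError(f"unknown subgroup dimension {dimension!r}")
        return self.df[col].to_numpy()

    # ---- derived cohorts -------------------------------------------------
    def take(self, rows: np.ndarray | Sequence[int]) -> "Cohort":
        """Positional row subset *without* re-validation.

        Used by resampling, where duplicated admission identifiers are
        legitimate in a bootstrap replicate.
        """
        return Cohort(self.df.take(list(rows)).reset_index(drop=True),
                      self.model_names, self.subgroup_dimensions, validate=False)

    def filter_subgroup(self, dimension: str, label: object) -> "Cohort":
        mask = self.subgroup(dimension) == label
        return self.take(np.flatnonzero(mask))

    def with_risk_column(self, model_name: str, risks: np.ndarray) -> "Cohort":
        if model_name in self.model_names:
            raise IntegrityError(f"model name {model_name!r} already present")
        df = self.df.copy()
        df[RISK_PREFIX + model_name] = np.asarray(risks, dtype=float)
        return Cohort(df, self.model_names + (model_name,),
                      self.subgroup_dimensions)

    # ---- construction ----------------------------------------------------
    @classmethod
    def from_arrays(cls, patient_id: Sequence, admission_id: Sequence,
                    eol: Sequence[int], cso: Sequence[int],
                    risks: Mapping[str, Sequence[float]] | None = None,
                    subgroups: Mapping[str, Sequence] | None = None,
                    admission_seq: Sequence[int] | None = None) -> "Cohort":
        data: dict = {
            "patient_id": list(patient_id),
            "admission_id": list(admission_id),
            "eol": np.asarray(eol, dtype=np.int64),
            "cso": np.asarray(cso, dtype=np.int64),
        }
        if admission_seq is not None:
            data[ORDER_KEY] = np.asarray(admission_seq, dtype=np.int64)
        risks = risks or {}
        for m, r in risks.items():
            data[RISK_PREFIX + m] = np.asarray(r, dtype=float)
        subgroups = subgroups or {}
        for d, g in subgroups.items():
            data[SUBGROUP_PREFIX + d] = list(g)
        return cls(pd.DataFrame(data), tuple(risks), tuple(subgroups))


def _apply_schema(df: pd.DataFrame, schema: Mapping | None) -> pd.DataFrame:
    """Rename columns and decode flag values according to an explicit schema.

    ``schema`` may contain a ``columns`` mapping (file column -> canonical
    column) and a ``flag_values`` mapping (raw value -> 0/1) applied to the
    eol and cso columns. Flags are accepted as literal 0/1 only unless a
    ``flag_values`` mapping declares another coding.
    """
    if schema is None:
        return df
    columns = schema.get("columns")
    if columns:
        df = df.rename(columns=dict(columns))
    flag_values = schema.get("flag_values")
    if flag_values:
        for flag in ("eol", "cso"):
            if flag in df.columns:
                mapped = df[flag].map(flag_values)
                unknown = mapped.isna() & df[flag].notna()
                if unknown.any():
                    row = int(np.flatnonzero(unknown.to_numpy())[0])
                    raise CohortValidationError(
                        f"{flag} value {df[flag].iloc[row]!r} in row {row} "
                        f"not covered by flag_values mapping")
                df = df.assign(**{flag: mapped.astype(np.int64)})
    return df


def read_cohort(path, schema: Mapping | None = None) -> Cohort:
    """Read a cohort CSV (UTF-8, header row required).

    Expected columns: ``patient_id``, ``admission_id``, ``eol``, ``cso``,
    at least one ``risk_<model>`` column, optional ``g_<dimension>`` columns
    and an optional ``admission_seq`` ordering key. ``schema`` may rename
    file columns to this layout and declare a non-0/1 flag coding.
    """
    df = pd.read_csv(path)
    df = _apply_schema(df, schema)
    model_names = tuple(c[len(RISK_PREFIX):] for c in df.columns
                        if c.startswith(RISK_PREFIX))
    dims = tuple(c[len(SUBGROUP_PREFIX):] for c in df.columns
                 if c.startswith(SUBGROUP_PREFIX))
    if not model_names:
        raise SchemaError(f"no {RISK_PREFIX}<model> column found")
    return Cohort(df, model_names, dims)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the canonical CSV schema."""
    cohort.df.to_csv(path, index=False)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_eol: int
    n_cso: int
    n_cso_and_eol: int
    subgroup_counts: dict


def cohort_summary(cohort: Cohort) -> CohortSummary:
    """Headline counts of a cohort (Table-2-style margins)."""
    if cohort.n == 0:
        raise EmptyCohortError("cannot summarise an empty cohort")
    eol = cohort.eol.astype(bool)
    cso = cohort.cso.astype(bool)
    sub: dict = {}
    for d in cohort.subgroup_dimensions:
        labels, counts = np.unique(cohort.subgroup(d), return_counts=True)
        sub[d] = {lab: int(c) for lab, c in zip(labels, counts)}
    return CohortSummary(
        n=cohort.n,
        n_eol=int(eol.sum()),
        n_cso=int(cso.sum()),
        n_cso_and_eol=int((eol & cso).sum()),
        subgroup_counts=sub,
    )
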