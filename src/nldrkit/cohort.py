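"""Cohort data model, table I/O and workload dichotomization.

A :class:`Cohort` wraps a pandas DataFrame with the canonical columns of
the variable registry, one row per donor.  Dichotomizing operative time
at a workload threshold (default 210 min, the cohort's 84.1th percentile,
i.e. mean + 1 SD under a normal model since Φ(1) ≈ 0.841) produces a
:class:`LabeledCohort` that separates heavy-workload ("difficult") from
moderate-workload ("easy") cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .registry import (
    COMPLICATION_COLUMN,
    CLAVIEN_RANKS,
    PREDICTOR_NAMES,
    TARGET,
    resolve_column,
)


class SchemaError(ValueError):
    """A required column is missing or cannot be resolved."""


class CohortParseError(ValueError):
    """A cell could not be parsed as the expected numeric type."""


@dataclass(frozen=True)
class DonorRecord:
    """One donor: operative time plus the 16 candidate predictors."""

    donor_id: str
    operative_time: float
    features: dict[str, float]
    complication_grade: str | None = None

    def vector(self, subset) -> np.ndarray:
        missing = [n for n in subset if n not in self.features]
        if missing:
            raise KeyError(f"missing features: {missing}")
        return np.array([self.features[n] for n in subset], dtype=float)


@dataclass
class Cohort:
    """An ordered collection of donor records backed by a DataFrame."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("cohort must contain at least one record")
        required = [TARGET.name, *PREDICTOR_NAMES]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table is missing columns: {missing}")
        if "donor_id" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "donor_id", [f"D{i:04d}" for i in range(len(self.df))])
        if self.df["donor_id"].duplicated().any():
            raise ValueError("donor_ids must be unique")
        if (self.df[TARGET.name] <= 0).any():
            raise ValueError("operative_time must be positive")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def operative_time(self) -> np.ndarray:
        return self.df[TARGET.name].to_numpy(dtype=float)

    def feature_matrix(self, subset=PREDICTOR_NAMES) -> np.ndarray:
        return self.df[list(subset)].to_numpy(dtype=float)

    def records(self) -> Iterator[DonorRecord]:
        for _, row in self.df.iterrows():
            grade = row.get(COMPLICATION_COLUMN)
            yield DonorRecord(
                donor_id=str(row["donor_id"]),
                operative_time=float(row[TARGET.name]),
                features={n: float(row[n]) for n in PREDICTOR_NAMES},
                complication_grade=None if grade is None or pd.isna(grade) else str(grade),
            )

    def complication_ranks(self) -> np.ndarray:
        """Complication grades as ordered integer ranks (0 = none)."""
        if COMPLICATION_COLUMN not in self.df.columns:
            raise SchemaError(f"cohort has no {COMPLICATION_COLUMN!r} column")
        col = self.df[COMPLICATION_COLUMN].astype(str).str.strip().str.lower()
        # tolerate floats like "2.0" written by spreadsheet round-trips
        col = col.str.replace(r"\.0$", "", regex=True)
        unknown = sorted(set(col) - set(CLAVIEN_RANKS))
        if unknown:
            raise CohortParseError(f"unknown complication grades: {unknown}")
        return col.map(CLAVIEN_RANKS).to_numpy(dtype=int)


@dataclass
class LabeledCohort:
    """A cohort dichotomized into difficult/easy workload groups."""

    cohort: Cohort
    threshold_min: float
    difficult: np.ndarray = field(repr=False)  # boolean, aligned with rows

    @property
    def n(self) -> int:
        return self.cohort.n

    @property
    def n_difficult(self) -> int:
        return int(self.difficult.sum())

    @property
    def n_easy(self) -> int:
        return int((~self.difficult).sum())

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.difficult, "difficult", "easy")


def dichotomize(cohort: Cohort, threshold_min: float = 210.0) -> LabeledCohort:
    """Label each donor difficult (operative time ≥ threshold) or easy.

    The rule is inclusive: a time exactly equal to the threshold is
    difficult.  A threshold leaving one group empty is allowed here but
    produces a warning; model fitting rejects such cohorts.
    """
    if threshold_min <= 0:
        raise ValueError("threshold_min must be positive")
    difficult = cohort.operative_time >= threshold_min
    if difficult.all() or not difficult.any():
        warnings.warn(
            f"threshold {threshold_min} min leaves one workload group empty",
            stacklevel=2,
        )
    return LabeledCohort(cohort=cohort, threshold_min=float(threshold_min),
                         difficult=difficult)


def percentile_threshold(cohort: Cohort, percentile: float) -> float:
    """Operative time at a percentile (linear interpolation convention).

    The value interpolates linearly between the closest order statistics
    (numpy's default), so it is monotone non-decreasing in the percentile.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    return float(np.percentile(cohort.operative_time, percentile, method="linear"))


def _resolve_headers(columns, schema: dict[str, str] | None) -> dict[str, str]:
    rename: dict[str, str] = {}
    for col in columns:
        canonical = resolve_column(str(col), schema)
        if canonical is not None and canonical not in rename.values():
            rename[col] = canonical
    return rename


def read_cohort(path, schema: dict[str, str] | None = None,
                sheet: str | int = 0) -> Cohort:
    """Read a cohort table from CSV or XLSX.

    Column headers are resolved against the canonical registry names and
    their clinical aliases; ``schema`` supplies extra source-column → canonical
    mappings.  Values are kept in their source units.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"empty cohort table: {path}")
    raw = raw.rename(columns=_resolve_headers(raw.columns, schema))
    required = [TARGET.name, *PREDICTOR_NAMES]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: cannot resolve required column(s) {missing}; "
            "provide a schema alias map"
        )
    keep = ["donor_id"] if "donor_id" in raw.columns else []
    keep += required
    if COMPLICATION_COLUMN in raw.columns:
        keep.append(COMPLICATION_COLUMN)
    df = raw[keep].copy()
    for col in required:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()].tolist()
            raise CohortParseError(
                f"{path.name}: non-numeric value in column {col!r} at row(s) {rows}"
            ) from exc
    incomplete = df[required].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"excluded {int(incomplete.sum())} record(s) with missing values",
            stacklevel=2,
        )
        df = df.loc[~incomplete].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no complete records in {path}")
    if "donor_id" in df.columns:
        df["donor_id"] = df["donor_id"].astype(str)
    return Cohort(df=df, provenance=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (full precision, round-trips bit-identically)."""
    path = Path(path)
    cohort.df.to_csv(path, index=False, float_format="%.17g")


def bmi(cohort: Cohort) -> np.ndarray:
    """Body-mass index, kg/m^2 (height is stored in cm)."""
    h_m = cohort.df["body_height"].to_numpy(dtype=float) / 100.0
    return cohort.df["body_weight"].to_numpy(dtype=float) / h_m**2
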