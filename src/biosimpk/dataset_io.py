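"""NONMEM-dialect rectangular event dataset: I/O, validation, exclusion rules.

Column dialect (CSV):

======  =======================================================
ID      subject identifier (int)
TIME    actual time, h (non-negative, non-decreasing per subject)
NTIM    nominal time, h (used for VPC binning)
AMT     dose amount, mg (dose rows only, else 0)
RATE    infusion rate, mg/h (dose rows only, else 0)
DV      observed concentration, mg/L (observation rows; 0 when missing)
EVID    1 = dose, 0 = observation
MDV     1 = DV missing/not usable, 0 = usable observation
BLQ     1 = observation below the quantification limit
CYCLE   1-based treatment cycle
TAG     nominal sampling tag ("C3_trough", "C1_peak", "EOT", ...)
======  =======================================================

plus covariate columns (BWT, SEX, PROD, and any extras), constant within
subject.  Categoricals are numeric codes (SEX: 0 female / 1 male; PROD:
0 reference product / 1 test product).

Two pre-modeling exclusion rules are implemented with a full audit trail:
first-cycle pre-dose samples with DV > 2 x LLOQ (discordant pre-dose
concentrations), and post-dose samples with DV < LLOQ (the "discard
post-dose BLQ" convention).  Exclusions never touch dose rows and are
idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PKDataset",
    "ExclusionReport",
    "DatasetError",
    "MANDATORY_COLUMNS",
    "read_dataset",
    "write_dataset",
    "apply_exclusions",
]

MANDATORY_COLUMNS = [
    "ID", "TIME", "NTIM", "AMT", "RATE", "DV", "EVID", "MDV", "BLQ", "CYCLE", "TAG",
]

_INT_COLUMNS = ["ID", "EVID", "MDV", "BLQ", "CYCLE"]


class DatasetError(ValueError):
    """Malformed dataset (missing columns, bad types, invariant violations)."""


@dataclass
class PKDataset:
    """Event table of all subjects plus per-row metadata.

    The underlying frame is the single source of truth; helper accessors
    provide the common views.  Covariate columns are every column not in
    the mandatory dialect.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- views ---------------------------------------------------------
    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in MANDATORY_COLUMNS]

    @property
    def subject_ids(self) -> list[int]:
        return list(dict.fromkeys(self.df["ID"].tolist()))

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def fit_observations(self) -> pd.DataFrame:
        """Rows that enter estimation: observed, usable, quantifiable."""
        d = self.df
        return d[(d["EVID"] == 0) & (d["MDV"] == 0) & (d["BLQ"] == 0)]

    def subject_covariates(self) -> pd.DataFrame:
        """One row per subject with the covariate columns (first occurrence)."""
        cols = ["ID"] + self.covariate_columns
        return self.df[cols].groupby("ID", sort=False).first().reset_index()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise DatasetError(f"missing mandatory columns: {missing}")
        df = self.df
        if len(df) == 0:
            return
        for col in ["TIME", "NTIM", "AMT", "RATE", "DV"]:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad[0]) if len(bad) else -1
                raise DatasetError(f"non-numeric {col} (first bad row index {row})")
        if (df["TIME"] < 0).any():
            row = int(df.index[df["TIME"] < 0][0])
            raise DatasetError(f"negative TIME at row index {row}")
        bad_dose = df[(df["EVID"] == 1) & (df["DV"] != 0)]
        if len(bad_dose):
            raise DatasetError(
                f"DV on a dose row at row index {int(bad_dose.index[0])}"
            )
        bad_amt = df[(df["EVID"] == 1) & (df["AMT"] <= 0)]
        if len(bad_amt):
            raise DatasetError(
                f"non-positive AMT on dose row index {int(bad_amt.index[0])}"
            )
        for sid, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise DatasetError(f"times not non-decreasing within subject {sid}")

    def copy(self) -> "PKDataset":
        return PKDataset(self.df.copy())

    @classmethod
    def trusted(cls, df: pd.DataFrame) -> "PKDataset":
        """Wrap a frame known to be valid (e.g. a row-gather of a validated
        dataset) without re-running validation."""
        obj = object.__new__(cls)
        obj.df = df
        return obj


@dataclass
class ExclusionReport:
    """Audit trail of the pre-modeling exclusion rules."""

    lloq: float
    n_before: int
    n_after: int
    predose_rows: list[int] = field(default_factory=list)  # rule (a) row indices
    blq_rows: list[int] = field(default_factory=list)  # rule (b) row indices
    n_postdose: int = 0  # denominator for the BLQ percentage

    @property
    def n_predose_excluded(self) -> int:
        return len(self.predose_rows)

    @property
    def n_blq_excluded(self) -> int:
        return len(self.blq_rows)

    @property
    def blq_percent(self) -> float:
        """Post-dose BLQ exclusions as % of all post-dose observations."""
        if self.n_postdose == 0:
            return 0.0
        return 100.0 * self.n_blq_excluded / self.n_postdose

    def summary(self) -> str:
        return (
            f"{self.n_predose_excluded} first-cycle pre-dose observations "
            f"> 2 x LLOQ ({2 * self.lloq:g} mg/L) excluded; "
            f"{self.n_blq_excluded} post-dose BLQ observations excluded "
            f"({self.n_blq_excluded} BLQ values out of {self.n_postdose} total "
            f"post-dose observations; {self.blq_percent:.2f}%). "
            f"Observations: {self.n_before} before, {self.n_after} after."
        )

    def to_dict(self) -> dict:
        return {
            "lloq": self.lloq,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_predose_excluded": self.n_predose_excluded,
            "n_blq_excluded": self.n_blq_excluded,
            "n_postdose": self.n_postdose,
            "blq_percent": round(self.blq_percent, 2),
            "predose_rows": self.predose_rows,
            "blq_rows": self.blq_rows,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def write_dataset(ds: PKDataset, path: str | Path) -> None:
    """Write the event table as CSV (lossless round trip with read_dataset)."""
    df = ds.df.copy()
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path: str | Path) -> PKDataset:
    """Read a CSV event table; raises DatasetError on dialect violations."""
    try:
        df = pd.read_csv(path, dtype={"TAG": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise DatasetError(f"cannot read dataset {path}: {exc}") from exc
    if len(df) == 0 and list(df.columns) == []:
        raise DatasetError(f"{path}: empty file without header")
    df["TAG"] = df.get("TAG", pd.Series(dtype=str)).fillna("")
    for col in _INT_COLUMNS:
        if col in df.columns and len(df):
            df[col] = df[col].astype(int)
    return PKDataset(df)


def impute_missing_covariates(ds: PKDataset) -> tuple[PKDataset, dict[str, float]]:
    """Median-impute missing continuous covariates; returns imputed medians.

    Imputed subjects are flagged in a companion column ``<COV>_IMP``.
    """
    df = ds.df.copy()
    medians: dict[str, float] = {}
    for col in ds.covariate_columns:
        if col.endswith("_IMP"):
            continue
        if df[col].isna().any():
            per_subject = df.groupby("ID", sort=False)[col].first()
            med = float(per_subject.median())
            medians[col] = med
            df[f"{col}_IMP"] = df[col].isna().astype(int)
            df[col] = df[col].fillna(med)
    return PKDataset(df), medians


def apply_exclusions(ds: PKDataset, lloq: float) -> tuple[PKDataset, ExclusionReport]:
    """Apply the two pre-modeling exclusion rules.

    (a) cycle-1 pre-dose observations with DV strictly greater than 2 x LLOQ
        (pre-dose samples at later cycles are never excluded);
    (b) post-dose observations with DV strictly below LLOQ.

    Rows are removed from the returned dataset; the report carries the row
    indices of both classes and the post-dose denominator used to express
    rule (b) as a percentage.  Dose rows are never removed.  Idempotent.
    """
    if lloq <= 0:
        raise ValueError(f"lloq must be positive, got {lloq}")
    df = ds.df
    obs = df["EVID"] == 0

    # pre-dose = observation at or before the subject's first dose time
    first_dose = df[df["EVID"] == 1].groupby("ID")["TIME"].min()
    fd = df["ID"].map(first_dose)
    predose = obs & (fd.isna() | (df["TIME"] <= fd))
    postdose = obs & ~predose

    rule_a = predose & (df["CYCLE"] == 1) & (df["DV"] > 2.0 * lloq) & (df["MDV"] == 0)
    rule_b = postdose & (df["DV"] < lloq) & (df["MDV"] == 0)

    n_before = int(obs.sum())
    keep = ~(rule_a | rule_b)
    out = PKDataset(df[keep].reset_index(drop=True))
    report = ExclusionReport(
        lloq=lloq,
        n_before=n_before,
        n_after=int((obs & keep).sum()),
        predose_rows=[int(i) for i in df.index[rule_a]],
        blq_rows=[int(i) for i in df.index[rule_b]],
        n_postdose=int((postdose & (df["MDV"] == 0)).sum()),
    )
    return out, report
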