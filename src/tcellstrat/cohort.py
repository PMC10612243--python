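"""Expression cohorts: a genes x patients matrix plus clinical annotations.

The :class:`ExpressionCohort` is the object both arms of the expression
pipeline operate on — the survival arm (overall survival in months with an
event indicator) and the therapy-response arm (RECIST-style labels CR, PR,
SD, PD).  Expression values are assumed to be normalized units; no
library-size or batch correction is performed here.

On disk a cohort is two tab-separated files:

* ``expr.tsv`` — genes x patients, first column ``gene`` holding the symbol,
  remaining columns one per patient.
* ``clinical.tsv`` — one row per patient with columns ``patient_id``,
  ``os_months``, ``os_event``, ``response`` (missing values left empty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError

VALID_RESPONSES = ("CR", "PR", "SD", "PD")

CLINICAL_COLUMNS = ("os_months", "os_event", "response")


@dataclass
class ExpressionCohort:
    """A patients x genes expression cohort with clinical annotations.

    Parameters
    ----------
    expression:
        Genes x patients matrix of finite, non-negative normalized
        expression values.  Index = gene symbols, columns = patient ids.
    clinical:
        Per-patient table indexed by patient id with (any subset of) the
        columns ``os_months`` (positive real), ``os_event`` (0/1) and
        ``response`` (one of CR/PR/SD/PD, or missing).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.clinical is None:
            self.clinical = pd.DataFrame(index=self.expression.columns)
        expr = self.expression
        if expr.index.duplicated().any():
            dups = expr.index[expr.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate gene symbols: {dups}")
        if expr.columns.duplicated().any():
            dups = expr.columns[expr.columns.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate patient ids: {dups}")
        vals = expr.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("expression contains non-finite values")
        if (vals < 0).any():
            raise ConfigurationError("expression contains negative values")
        if not expr.columns.equals(self.clinical.index):
            missing = expr.columns.difference(self.clinical.index).tolist()
            extra = self.clinical.index.difference(expr.columns).tolist()
            if missing or extra:
                raise ConfigurationError(
                    f"clinical table does not match expression columns "
                    f"(missing={missing[:5]}, extra={extra[:5]})"
                )
            # same set, different order: align
            self.clinical = self.clinical.loc[expr.columns]
        if "response" in self.clinical:
            bad = self.clinical["response"].dropna()
            bad = bad[~bad.isin(VALID_RESPONSES)]
            if len(bad):
                raise ConfigurationError(
                    f"invalid response labels: {sorted(bad.unique())}"
                )

    # ------------------------------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    def subset(self, patients: Iterable[str]) -> "ExpressionCohort":
        """Return the cohort restricted to ``patients`` (order preserved)."""
        patients = pd.Index(patients)
        missing = patients.difference(self.patient_ids)
        if len(missing):
            raise KeyError(f"unknown patients: {missing.tolist()[:5]}")
        return ExpressionCohort(
            expression=self.expression.loc[:, patients],
            clinical=self.clinical.loc[patients],
        )

    def has_survival(self) -> bool:
        return {"os_months", "os_event"}.issubset(self.clinical.columns)

    def survival_complete(self) -> pd.Series:
        """Boolean mask of patients with both os_months and os_event."""
        if not self.has_survival():
            return pd.Series(False, index=self.patient_ids)
        return (
            self.clinical["os_months"].notna() & self.clinical["os_event"].notna()
        )


# ----------------------------------------------------------------------
# Disk round-trip


def write_cohort(cohort: ExpressionCohort, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``expr.tsv`` and ``clinical.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "expr.tsv"
    clin_path = outdir / "clinical.tsv"
    cohort.expression.to_csv(expr_path, sep="\t", index_label="gene")
    clin = cohort.clinical.copy()
    for col in CLINICAL_COLUMNS:
        if col not in clin:
            clin[col] = np.nan
    clin[list(CLINICAL_COLUMNS)].to_csv(clin_path, sep="\t", index_label="patient_id")
    return expr_path, clin_path


def read_cohort(
    expr_path: str | Path, clinical_path: str | Path | None = None
) -> ExpressionCohort:
    """Read a cohort from ``expr.tsv`` (and optionally ``clinical.tsv``)."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    clinical = None
    if clinical_path is not None:
        clinical = pd.read_csv(clinical_path, sep="\t", index_col=0)
        clinical.index = clinical.index.astype(str)
        if "os_event" in clinical:
            clinical["os_event"] = clinical["os_event"].astype("float").astype("Int64")
    return ExpressionCohort(expression=expr, clinical=clinical)
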