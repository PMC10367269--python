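"""Patient-by-diagnosis matrices.

The root input of the pipeline is a binary patient x disease occurrence
matrix (1 = the patient has a record of the disease) together with
per-patient covariates (age, sex, subtype label). Disease codes are opaque
strings; no vocabulary semantics are attached to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["DiagnosisMatrix"]


@dataclass
class DiagnosisMatrix:
    """Sparse binary patients x diseases matrix with covariates.

    Parameters
    ----------
    patients : list of str
        Ordered unique patient identifiers (row labels).
    diseases : list of str
        Ordered unique disease codes (column labels).
    occurrence : scipy.sparse.csr_matrix
        Binary matrix, shape ``(n_patients, n_diseases)``.
    covariates : pandas.DataFrame
        One row per patient, indexed by patient id. Conventional columns
        are ``age`` (years or ordered age-group label), ``sex`` and
        ``subtype``; extra columns are carried along untouched.
    """

    patients: list[str]
    diseases: list[str]
    occurrence: sp.csr_matrix
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.occurrence = sp.csr_matrix(self.occurrence, dtype=np.int8)
        n, d = self.occurrence.shape
        if n != len(self.patients) or d != len(self.diseases):
            raise ValueError("occurrence shape does not match label lists")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("patient ids must be unique")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("disease codes must be unique")
        if self.occurrence.nnz and not np.isin(self.occurrence.data, (0, 1)).all():
            raise ValueError("occurrence entries must be binary")
        if len(self.covariates) and not self.covariates.index.equals(
            pd.Index(self.patients)
        ):
            self.covariates = self.covariates.reindex(self.patients)

    # ------------------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def prevalence(self) -> pd.Series:
        """Number of patients with a record of each disease."""
        counts = np.asarray(self.occurrence.sum(axis=0)).ravel()
        return pd.Series(counts, index=self.diseases, name="prevalence")

    def column(self, disease: str) -> np.ndarray:
        """Dense binary indicator vector of one disease."""
        j = self.diseases.index(disease)
        return np.asarray(self.occurrence[:, j].todense()).ravel()

    def validate(self) -> None:
        """Raise if any disease has zero prevalence (degenerate column)."""
        prev = self.prevalence()
        empty = prev[prev == 0]
        if len(empty):
            raise ValueError(
                f"{len(empty)} disease(s) with zero prevalence: "
                f"{list(empty.index[:5])}..."
            )

    # ------------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long-format table of (patient_id, disease_code) records."""
        coo = self.occurrence.tocoo()
        return pd.DataFrame(
            {
                "patient_id": np.asarray(self.patients, dtype=object)[coo.row],
                "disease_code": np.asarray(self.diseases, dtype=object)[coo.col],
            }
        ).sort_values(["patient_id", "disease_code"], ignore_index=True)

    @classmethod
    def from_long(
        cls,
        records: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        patients: list[str] | None = None,
        diseases: list[str] | None = None,
    ) -> "DiagnosisMatrix":
        """Build from a long-format (patient_id, disease_code) table.

        Patients present in ``covariates`` but without any record are kept
        as all-zero rows, matching how cohorts include disease-free
        patients.
        """
        if patients is None:
            seen = list(pd.unique(records["patient_id"]))
            if covariates is not None:
                extra = [p for p in covariates.index if p not in set(seen)]
                patients = seen + extra
            else:
                patients = seen
        if diseases is None:
            diseases = sorted(pd.unique(records["disease_code"]))
        p_idx = {p: i for i, p in enumerate(patients)}
        d_idx = {d: j for j, d in enumerate(diseases)}
        rows = records["patient_id"].map(p_idx).to_numpy()
        cols = records["disease_code"].map(d_idx).to_numpy()
        mat = sp.coo_matrix(
            (np.ones(len(records), dtype=np.int8), (rows, cols)),
            shape=(len(patients), len(diseases)),
        ).tocsr()
        mat.data = np.minimum(mat.data, 1)  # collapse duplicate records
        cov = covariates if covariates is not None else pd.DataFrame(index=patients)
        return cls(list(patients), list(diseases), mat, cov)

    # ------------------------------------------------------------------
    def write(self, records_path: str | Path, covariates_path: str | Path) -> None:
        self.to_long().to_csv(records_path, sep="\t", index=False)
        self.covariates.to_csv(covariates_path, sep="\t", index_label="patient_id")

    @classmethod
    def read(
        cls, records_path: str | Path, covariates_path: str | Path | None = None
    ) -> "DiagnosisMatrix":
        records = pd.read_csv(records_path, sep="\t", dtype=str)
        cov = None
        if covariates_path is not None:
            cov = pd.read_csv(covariates_path, sep="\t", index_col="patient_id")
        return cls.from_long(records, covariates=cov)

    def subset_patients(self, mask: np.ndarray) -> "DiagnosisMatrix":
        """Row subset by boolean mask, covariates kept aligned."""
        idx = np.flatnonzero(mask)
        return DiagnosisMatrix(
            [self.patients[i] for i in idx],
            list(self.diseases),
            self.occurrence[idx],
            self.covariates.iloc[idx] if len(self.covariates) else self.covariates,
        )
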