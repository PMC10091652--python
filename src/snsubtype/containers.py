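"""Shared data containers for the subtyping pipeline.

Expression matrices are oriented genes x cells (features x samples)
throughout, matching the on-disk MatrixMarket layout. Cell metadata and
patient metadata travel alongside the matrix so that every downstream
stage (gene-set scoring, fusion, differential expression, clinical
association) can reach the covariates it adjusts for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_COLUMNS = ("patient_id", "diagnosis", "cell_type", "region", "batch", "ribo_fraction")
PATIENT_COLUMNS = ("age", "sex", "RIN", "PMI")


@dataclass
class CellExpressionMatrix:
    """Log-normalized expression with per-cell and per-patient covariates.

    Attributes
    ----------
    values : pd.DataFrame
        genes x cells, log2 scale, finite and >= 0.
    cells : pd.DataFrame
        Indexed by cell_id; columns include patient_id, diagnosis
        ("case"/"control"), cell_type, region, batch, ribo_fraction and
        detection_rate (fraction of genes detected in the cell).
    patients : pd.DataFrame
        Indexed by patient_id; columns age, sex, RIN, PMI.
    """

    values: pd.DataFrame
    cells: pd.DataFrame
    patients: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> "CellExpressionMatrix":
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene_ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell_ids")
        if not self.values.columns.equals(self.cells.index):
            raise ValueError("cell metadata index does not match matrix columns")
        missing = set(self.cells["patient_id"]) - set(self.patients.index)
        if missing:
            raise ValueError(f"cells reference patients without metadata: {sorted(missing)}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite expression values")
        if (vals < 0).any():
            raise ValueError("negative expression values")
        return self

    def subset_cells(self, mask: pd.Series | np.ndarray) -> "CellExpressionMatrix":
        cells = self.cells.loc[mask]
        return CellExpressionMatrix(self.values.loc[:, cells.index], cells, self.patients)

    def subset_genes(self, gene_ids) -> "CellExpressionMatrix":
        return CellExpressionMatrix(self.values.loc[list(gene_ids)], self.cells, self.patients)


@dataclass
class SetScoreMatrix:
    """Gene-set enrichment scores, sets x cells; cell metadata shared
    with the expression matrix the scores were computed from."""

    values: pd.DataFrame
    cells: pd.DataFrame
    patients: pd.DataFrame

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PatientProfileMatrix:
    """Patients x features mean profiles for one cell type.

    feature_kind is "gene" or "gene_set"; rows are patients that had at
    least one cell of the cell type.
    """

    values: pd.DataFrame
    feature_kind: str
    cell_type: str


@dataclass
class AffinityMatrix:
    """Symmetric patient-patient similarity.

    `normalized` distinguishes the raw kernel (diag = 1) from the
    row-stochastic form used in cross-diffusion (diag = 1/2, rows sum
    to 1 exactly). Row-stochastic matrices derived from a symmetric
    kernel are only approximately symmetric (rows are scaled by
    different degrees), so the symmetry check is looser for them.
    """

    values: np.ndarray
    patient_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.patient_ids):
            raise ValueError("affinity matrix shape does not match patient ids")
        if not self.normalized and not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("affinity matrix not symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("negative affinities")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.patient_ids)


@dataclass
class SubtypeAssignment:
    """Cluster labels (1..k) per patient plus model-selection diagnostics."""

    labels: pd.Series          # patient_id -> label in 1..k
    k: int
    silhouette: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def patients_in(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def validate(self) -> "SubtypeAssignment":
        present = set(self.labels)
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels {sorted(present)} do not cover 1..{self.k}")
        return self
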