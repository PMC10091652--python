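"""Normalization, gene filtering, HVG selection, and patient profiles.

Size factors are median-ratio library-size factors: s_c = library size
of cell c divided by the median library size, and the normalized value
is log2(count / s_c + 1). This is a deliberately simple, documented
stand-in for pooling-deconvolution factors; every downstream stage only
requires a log-normalized matrix.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellExpressionMatrix, PatientProfileMatrix, SetScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDE_PATTERNS = ("^MT-", "^RP[LS]")


def normalize_log(counts, gene_ids, cells: pd.DataFrame, patients: pd.DataFrame) -> CellExpressionMatrix:
    """Library-size normalize and log2 transform a count matrix.

    Parameters
    ----------
    counts : genes x cells nonnegative integer matrix (sparse or dense).
    gene_ids, cells, patients : identifiers and metadata; `cells` rows
        must align with the matrix columns.

    detection_rate (fraction of genes with count > 0) is recomputed and
    stored in the cell metadata.
    """
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if counts.shape[1] != len(cells):
        raise ValueError(f"counts has {counts.shape[1]} cells, metadata has {len(cells)}")

    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(f"cells with zero library size: {list(cells.index[zero[:10]])}")
    size_factor = libsize / np.median(libsize)
    values = np.log2(counts / size_factor[None, :] + 1.0)

    cells = cells.copy()
    cells["detection_rate"] = (counts > 0).mean(axis=0)
    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=cells.index)
    return CellExpressionMatrix(frame, cells, patients).validate()


def select_hvg(expr: CellExpressionMatrix, n_top: int,
               exclude_patterns=DEFAULT_EXCLUDE_PATTERNS) -> CellExpressionMatrix:
    """Keep the n_top most variable genes (variance of log expression).

    Genes matching any exclusion regex are removed before ranking.
    Original gene order is preserved within the kept set.
    """
    regexes = [re.compile(p) for p in (exclude_patterns or [])]
    keep = [g for g in expr.gene_ids if not any(r.search(g) for r in regexes)]
    if n_top > len(keep):
        raise ValueError(f"n_top={n_top} exceeds {len(keep)} genes available after exclusion")
    sub = expr.values.loc[keep]
    variances = sub.var(axis=1, ddof=1)
    # stable: ties resolved by input order
    order = np.argsort(-variances.to_numpy(), kind="stable")[:n_top]
    chosen = set(np.asarray(keep, dtype=object)[order])
    kept = [g for g in keep if g in chosen]
    return expr.subset_genes(kept)


def patient_mean_profiles(data: CellExpressionMatrix | SetScoreMatrix, cell_type: str,
                          patients: list[str] | None = None) -> PatientProfileMatrix:
    """Average each patient's cells of one cell type into a profile row.

    Patients with zero cells of the type are omitted with a warning.
    """
    cells = data.cells
    mask = cells["cell_type"] == cell_type
    if not mask.any():
        raise ValueError(f"no cells of cell type {cell_type!r}")
    sub_cells = cells.loc[mask]
    sub_values = data.values.loc[:, sub_cells.index]
    wanted = patients if patients is not None else list(pd.unique(sub_cells["patient_id"]))
    rows = {}
    for pid in wanted:
        idx = sub_cells.index[sub_cells["patient_id"] == pid]
        if len(idx) == 0:
            logger.warning("patient %s has no %s cells; omitted from profiles", pid, cell_type)
            continue
        rows[pid] = sub_values[idx].mean(axis=1)
    kind = "gene_set" if isinstance(data, SetScoreMatrix) else "gene"
    profile = pd.DataFrame(rows).T
    profile.index.name = "patient_id"
    return PatientProfileMatrix(profile, feature_kind=kind, cell_type=cell_type)
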