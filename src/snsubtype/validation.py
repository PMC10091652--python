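"""Cross-dataset subtype correspondence.

Subtypes derived independently on a second expression matrix (bulk or
pseudo-bulk) are related to the single-nucleus subtypes by correlating
per-gene fold-change signatures: for each subtype system, each
subtype's per-gene log2 fold change vs the remaining subtypes is
computed from individual-level mean expression, and every (sn subtype,
bulk subtype) pair gets a Pearson r and p over the shared genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellExpressionMatrix, SubtypeAssignment

logger = logging.getLogger(__name__)


def subtype_fold_changes(expr: CellExpressionMatrix | pd.DataFrame,
                         assignment: SubtypeAssignment,
                         combine_cell_types: bool = False,
                         cell_type: str | None = None) -> pd.DataFrame:
    """Per-gene log2 fold change of each subtype vs the other subtypes.

    For cell-level input, cells are first averaged per individual
    (within one cell type, or across all cell types when
    combine_cell_types is set); fold change is the mean of the
    subtype's individual profiles minus the mean of the remaining
    individuals'. For a patients x genes frame the rows are used as the
    individual profiles directly. Returns genes x subtypes.
    """
    labels = assignment.labels
    if labels.nunique() < 2:
        raise ValueError("need >= 2 subtypes")
    if isinstance(expr, CellExpressionMatrix):
        cells = expr.cells
        mask = np.ones(len(cells), dtype=bool)
        if not combine_cell_types:
            if cell_type is None:
                raise ValueError("pass cell_type or combine_cell_types=True")
            mask = (cells["cell_type"] == cell_type).to_numpy()
        sub = expr.values.loc[:, cells.index[mask]]
        sub_cells = cells.loc[mask]
        profiles = {}
        for pid in labels.index:
            idx = sub_cells.index[sub_cells["patient_id"] == pid]
            if len(idx) == 0:
                logger.warning("patient %s has no cells for fold-change profiles", pid)
                continue
            profiles[pid] = sub[idx].mean(axis=1)
        prof = pd.DataFrame(profiles).T
    else:
        prof = expr.loc[[p for p in labels.index if p in expr.index]]

    out = {}
    for s in sorted(labels.unique()):
        in_s = [p for p in prof.index if labels[p] == s]
        out_s = [p for p in prof.index if labels[p] != s]
        if len(in_s) == 1:
            logger.warning("subtype %s has a single individual; fold change still computed", s)
        out[s] = prof.loc[in_s].mean(axis=0) - prof.loc[out_s].mean(axis=0)
    fc = pd.DataFrame(out)
    fc.index.name = "gene_id"
    return fc


def correspondence_matrix(fc_sn: pd.DataFrame, fc_bulk: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p between every (sn subtype, bulk subtype) pair of
    fold-change vectors over the shared gene universe."""
    shared = fc_sn.index.intersection(fc_bulk.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    logger.info("correspondence computed over %d shared genes", len(shared))
    a = fc_sn.loc[shared]
    b = fc_bulk.loc[shared]
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    p = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for i in a.columns:
        for j in b.columns:
            x = a[i].to_numpy(dtype=float)
            y = b[j].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning("zero-variance fold-change vector for pair (%s, %s); NA", i, j)
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[i, j] = rr
            p.loc[i, j] = pp
    r.index.name = "sn_subtype"
    p.index.name = "sn_subtype"
    return r, p


def match_subtypes(r: pd.DataFrame) -> dict:
    """Row-wise argmax pairing: each sn subtype's best-correlated bulk
    subtype."""
    return {i: r.loc[i].astype(float).idxmax() for i in r.index}
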