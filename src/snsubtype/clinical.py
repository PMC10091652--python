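"""Clinical-score construction and subtype association.

The combined clinical score of a patient is the mean of their
within-category ranks over the five ADI-R-style categories (A,
B-verbal, B-nonverbal, C, D). Subtype-specific feature sets are related
to clinical severity by correlating per-patient expression fold
changes (each case vs the control group, hurdle convention) with the
combined score and combining the per-gene correlation p-values with
Fisher's method. Per-category differences between one subtype and the
rest are tested with Welch t-tests on the ranks, BH-corrected across
categories. Risk-gene enrichment of subtype-specific features uses the
hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CellExpressionMatrix, SubtypeAssignment

logger = logging.getLogger(__name__)

CATEGORIES = ["A", "B_verbal", "B_nonverbal", "C", "D"]


@dataclass
class ClinicalParams:
    """min_degs: smallest subtype-specific feature list worth a meta
    p-value (cell types below it report NA); min_degs_small: the
    relaxed floor applied where configured; meta_alpha: significance
    threshold on the Fisher meta p-value."""

    min_degs: int = 10
    min_degs_small: int = 5
    meta_alpha: float = 0.1

    def validate(self) -> "ClinicalParams":
        if self.min_degs_small > self.min_degs:
            raise ValueError("min_degs_small must be <= min_degs")
        return self


def combined_score(raw: pd.DataFrame) -> pd.Series:
    """Mean of within-category average ranks, over non-missing categories.

    Patients missing every category are excluded with a warning.
    """
    if len(raw) < 2:
        raise ValueError("need >= 2 patients")
    ranks = raw.rank(axis=0, method="average", na_option="keep")
    combined = ranks.mean(axis=1, skipna=True)
    dropped = combined[combined.isna()]
    if len(dropped):
        logger.warning("patients with no clinical data excluded: %s", list(dropped.index))
    return combined.dropna().rename("combined_score")


def individual_fold_changes(expr: CellExpressionMatrix, patient: str,
                            control_mask: np.ndarray, gene_list: list[str]) -> pd.Series:
    """Per-gene hurdle log2 fold change of one patient's cells vs the
    control cells (detection frequency x conditional mean contrast,
    unadjusted: with a single patient on one side, patient-level
    covariates are confounded with the contrast and not estimable)."""
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() == 0:
        raise ValueError("empty control group")
    pat_mask = (expr.cells["patient_id"] == patient).to_numpy()
    if pat_mask.sum() < 3:
        raise ValueError(f"patient {patient} has fewer than 3 cells")
    vals = expr.values.loc[gene_list]
    out = {}
    for g in gene_list:
        y = vals.loc[g].to_numpy()
        out[g] = _hurdle_group_fc(y[pat_mask], y[control_mask])
    return pd.Series(out, name=patient)


def _hurdle_group_fc(y1: np.ndarray, y0: np.ndarray) -> float:
    pi1 = float((y1 > 0).mean())
    pi0 = float((y0 > 0).mean())
    m1 = float(y1[y1 > 0].mean()) if (y1 > 0).any() else 0.0
    m0 = float(y0[y0 > 0].mean()) if (y0 > 0).any() else 0.0
    return pi1 * m1 - pi0 * m0


def gene_clinical_correlation(fc: pd.DataFrame, combined: pd.Series) -> pd.DataFrame:
    """Pearson r and two-sided p per gene between per-patient fold
    changes (patients x genes) and combined clinical scores."""
    shared = fc.index.intersection(combined.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 patients with fold changes and clinical scores")
    x = combined.loc[shared].to_numpy(dtype=float)
    rows = {}
    for g in fc.columns:
        y = fc.loc[shared, g].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            logger.warning("gene %s has zero-variance fold changes; excluded", g)
            continue
        r, p = stats.pearsonr(y, x)
        rows[g] = {"r": float(r), "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")


def fisher_meta(p_values) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2m df under
    the null of independent uniform p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("p-value of 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def category_rank_ttests(clinical: pd.DataFrame, assignment: SubtypeAssignment) -> pd.DataFrame:
    """Welch t-tests on within-category score ranks, each subtype vs
    all other subtypes, BH-corrected across the categories per subtype."""
    ranks = clinical.rank(axis=0, method="average", na_option="keep")
    labels = assignment.labels.loc[[p for p in clinical.index if p in assignment.labels.index]]
    rows = []
    for s in sorted(labels.unique()):
        in_s = labels.index[labels == s]
        out_s = labels.index[labels != s]
        for cat in clinical.columns:
            a = ranks.loc[in_s, cat].dropna()
            b = ranks.loc[out_s, cat].dropna()
            if len(a) < 2 or len(b) < 2 or (a.var() == 0 and b.var() == 0):
                rows.append({"subtype": s, "category": cat, "t": np.nan, "p": np.nan,
                             "flag": "degenerate"})
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"subtype": s, "category": cat, "t": float(t), "p": float(p), "flag": ""})
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for s in table["subtype"].unique():
        mask = (table["subtype"] == s) & table["p"].notna()
        if mask.any():
            table.loc[mask, "fdr"] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
    return table


def hypergeom_enrichment(query, reference, universe) -> dict:
    """Over-representation of `reference` (e.g., risk genes) in `query`
    (e.g., subtype-specific features) against `universe`.

    p = P(X >= overlap), X ~ Hypergeom(|universe|, |reference|, |query|);
    fold = observed/expected overlap.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    reference = set(reference) & universe
    overlap = len(query & reference)
    M, n, N = len(universe), len(reference), len(query)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    expected = N * n / M if M else np.nan
    fold = overlap / expected if expected > 0 else np.nan
    return {"overlap": overlap, "p": p, "fold": fold,
            "query_size": N, "reference_size": n, "universe_size": M}


def meta_correlation_report(deg_tables: dict[tuple[int, str], list[str]],
                            fc_matrices: dict[str, pd.DataFrame],
                            combined: pd.Series,
                            params: ClinicalParams | None = None,
                            small_filter_subtypes: set[int] = frozenset(),
                            ) -> pd.DataFrame:
    """Fisher meta p-value of feature-clinical correlations per
    (subtype, cell type).

    deg_tables maps (subtype, cell_type) to its subtype-specific
    feature list; fc_matrices maps cell_type to a patients x genes
    fold-change matrix. Cell types whose feature list is shorter than
    the applicable filter (min_degs, or min_degs_small for subtypes in
    `small_filter_subtypes`) are reported as NA.
    """
    params = (params or ClinicalParams()).validate()
    rows = []
    for (s, t), genes in sorted(deg_tables.items()):
        floor = params.min_degs_small if s in small_filter_subtypes else params.min_degs
        if len(genes) < floor:
            rows.append({"subtype": s, "cell_type": t, "n_features": len(genes),
                         "meta_p": np.nan, "significant": False, "note": "NA_below_min_degs"})
            continue
        fc = fc_matrices[t]
        present = [g for g in genes if g in fc.columns]
        corr = gene_clinical_correlation(fc[present], combined)
        meta = fisher_meta(corr["p"])
        rows.append({"subtype": s, "cell_type": t, "n_features": len(genes),
                     "meta_p": meta, "significant": bool(meta < params.meta_alpha), "note": ""})
    return pd.DataFrame(rows)


def read_risk_genes(path) -> list[str]:
    from .io import read_gene_list

    return read_gene_list(path)
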