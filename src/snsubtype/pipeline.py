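"""End-to-end orchestration of the two-level subtyping workflow.

Stage order: load -> normalize/log -> gene-set scoring -> per-cell-type
patient profiles (genes and gene sets) -> SNF within each modality
across cell types -> SNF across the two modality networks -> cluster
number selection + spectral clustering -> differential genes (hurdle)
and gene sets (moderated lm) per subtype -> subtype-specific
intersection, unique/common partition, discordance screen -> clinical
association -> pseudo-bulk correspondence -> PLS-DA prediction. Every
stage writes its tables under the output directory and is recorded in
manifest.json with the parameters and seeds that produced it; a rerun
with the same config and seed reproduces identical files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .clinical import (ClinicalParams, category_rank_ttests, combined_score,
                       hypergeom_enrichment, individual_fold_changes,
                       meta_correlation_report)
from .containers import AffinityMatrix, CellExpressionMatrix, SubtypeAssignment
from .diffexpr import (DEThresholds, build_design, de_features,
                       discordant_events, partition_unique_common,
                       subtype_specific)
from .gsva import GSVAParams, gsva_scores
from .prediction import PredictionParams, run_prediction
from .preprocess import normalize_log, patient_mean_profiles, select_hvg
from .snf import (SNFParams, affinity_matrix, estimate_n_clusters,
                  silhouette_from_affinity, snf_fuse, spectral_cluster,
                  squared_euclidean_distances)
from .synthetic import Cohort, read_cohort
from .validation import correspondence_matrix, match_subtypes, subtype_fold_changes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "snsubtype_out"
    data_dir: str | None = None
    seed: int = 0
    n_hvg: int | None = None
    exclude_patterns: tuple[str, ...] = ()
    gsva: GSVAParams = field(default_factory=GSVAParams)
    snf: SNFParams = field(default_factory=SNFParams)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    component_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    cv_repeats: int = 10
    fixed_k: int | None = None
    risk_genes: list[str] | None = None
    bulk: pd.DataFrame | None = None
    with_prediction: bool = True
    prediction_cell_types: tuple[str, ...] | None = None
    de_covariates: tuple[str, ...] = ("detection_rate", "age", "sex", "RIN", "PMI",
                                      "region", "batch", "ribo_fraction")


@dataclass
class PipelineResult:
    expr: dict[str, CellExpressionMatrix]
    scores: dict
    fused_gene: AffinityMatrix
    fused_set: AffinityMatrix
    fused_final: AffinityMatrix
    assignment: SubtypeAssignment
    modality_assignments: dict
    de_tables: dict
    subtype_specific_tables: dict
    unique_common: dict
    discordance: dict
    clinical_report: dict
    validation_report: dict
    prediction_reports: list
    manifest: dict


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed,
                      "params": {
                          "gsva": vars(config.gsva), "snf": vars(config.snf),
                          "thresholds": vars(config.thresholds),
                          "clinical": vars(config.clinical),
                          "n_hvg": config.n_hvg,
                          "component_grid": list(config.component_grid),
                      }}

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage %s", name)
        return time.time()

    def fail(name, exc):
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # ------------------------------------------------------------------ load
    stage("load")
    if cohort is None:
        if config.data_dir is None:
            raise ValueError("need either a cohort object or data_dir")
        cohort = read_cohort(config.data_dir)
    cell_types = sorted(cohort.counts)

    # ------------------------------------------------------------ preprocess
    stage("preprocess")
    expr: dict[str, CellExpressionMatrix] = {}
    for t in cell_types:
        cells_t = cohort.cells_of(t)
        e = normalize_log(cohort.counts[t], cohort.gene_ids, cells_t, cohort.patients)
        if config.n_hvg is not None:
            e = select_hvg(e, config.n_hvg, config.exclude_patterns)
        expr[t] = e

    # ------------------------------------------------------------------ gsva
    stage("gsva")
    scores = {t: gsva_scores(expr[t], cohort.gene_sets, config.gsva) for t in cell_types}

    # -------------------------------------------------------------- profiles
    stage("profiles")
    case_ids = list(cohort.patients.index[cohort.patients["diagnosis"] == "case"])
    gene_profiles, set_profiles = {}, {}
    for t in cell_types:
        case_expr = expr[t].subset_cells(expr[t].cells["diagnosis"] == "case")
        gene_profiles[t] = patient_mean_profiles(case_expr, t, patients=case_ids)
        case_scores_vals = scores[t].values.loc[:, case_expr.cells.index]
        from .containers import SetScoreMatrix
        case_scores = SetScoreMatrix(case_scores_vals, case_expr.cells, cohort.patients)
        set_profiles[t] = patient_mean_profiles(case_scores, t, patients=case_ids)

    # ---------------------------------------------------------- snf_modality
    stage("snf_modality")
    snf_params = config.snf
    def fuse_views(profiles):
        views = []
        for t in cell_types:
            d = squared_euclidean_distances(profiles[t], standardize=snf_params.standardize)
            views.append(affinity_matrix(d, K=snf_params.K, mu=snf_params.mu, kernel=snf_params.kernel))
        return snf_fuse(views, snf_params)

    fused_gene = fuse_views(gene_profiles)
    fused_set = fuse_views(set_profiles)

    # ------------------------------------------------------------- snf_final
    stage("snf_final")
    def as_raw(P: AffinityMatrix) -> AffinityMatrix:
        w = (P.values + P.values.T) / 2.0
        return AffinityMatrix(w, P.patient_ids, normalized=False)

    fused_final = snf_fuse([as_raw(fused_gene), as_raw(fused_set)], snf_params)

    # ------------------------------------------------------------ clustering
    stage("clustering")
    modality_assignments = {}
    diagnostics_all = {}
    for name, P in (("gene", fused_gene), ("set", fused_set), ("final", fused_final)):
        k_eig, k_rot, diag = estimate_n_clusters(P, snf_params.k_range)
        k = config.fixed_k if config.fixed_k is not None else k_eig
        assign = spectral_cluster(P, k, seed=snf_params.seed)
        assign.silhouette = silhouette_from_affinity(P, assign.labels)
        assign.diagnostics = {**diag, "k_eigengap": k_eig, "k_rotation": k_rot}
        modality_assignments[name] = assign
        diagnostics_all[name] = assign.diagnostics
    assignment = modality_assignments["final"]
    sio.write_tsv(assignment.labels.to_frame(), out / "subtype_labels.tsv")
    sio.write_tsv(fused_final.to_frame(), out / "fused_affinity.tsv")
    sio.write_json({"silhouettes": {n: a.silhouette for n, a in modality_assignments.items()},
                    "k": assignment.k, "diagnostics": diagnostics_all},
                   out / "clustering.json")

    # -------------------------------------------------------------- diffexpr
    stage("diffexpr")
    subtype_of = {p: int(s) for p, s in assignment.labels.items()}
    de_tables: dict = {}
    for t in cell_types:
        e = expr[t]
        sc = scores[t]
        case_mask = (e.cells["diagnosis"] == "case").to_numpy()
        cell_subtype = e.cells["patient_id"].map(lambda p: subtype_of.get(p, 0)).to_numpy()
        for s in range(1, assignment.k + 1):
            for comparison in ("vs_other_subtypes", "vs_controls"):
                if comparison == "vs_other_subtypes":
                    sel = case_mask
                else:
                    sel = (cell_subtype == s) | (~case_mask)
                grp = (cell_subtype == s)[sel]
                cells_sel = e.cells.loc[sel]
                design = build_design(cells_sel, e.patients, config.de_covariates)
                gene_tab = de_features(e.values.loc[:, cells_sel.index], grp, design,
                                       config.thresholds, "hurdle", kind="gene",
                                       cell_type=t, subtype=s, comparison=comparison,
                                       keep_all=True)
                set_tab = de_features(sc.values.loc[:, cells_sel.index], grp, design,
                                      config.thresholds, "moderated", kind="gene_set",
                                      cell_type=t, subtype=s, comparison=comparison,
                                      keep_all=True)
                de_tables[(t, s, comparison)] = pd.concat([gene_tab, set_tab], ignore_index=True)

    # ------------------------------------------------------ subtype_specific
    stage("subtype_specific")
    specific: dict = {}
    for t in cell_types:
        for s in range(1, assignment.k + 1):
            for kind in ("gene", "gene_set"):
                a = _sig(de_tables[(t, s, "vs_other_subtypes")], kind)
                b = _sig(de_tables[(t, s, "vs_controls")], kind)
                specific[(t, s, kind)] = subtype_specific(a, b)
    unique_common: dict = {}
    discordance: dict = {}
    for t in cell_types:
        for kind in ("gene", "gene_set"):
            tables = {s: specific[(t, s, kind)] for s in range(1, assignment.k + 1)}
            uniq, common, top = partition_unique_common(tables)
            unique_common[(t, kind)] = {"unique": uniq, "common": common, "top": top}
            fc_ctrl = pd.DataFrame({
                s: de_tables[(t, s, "vs_controls")]
                    .loc[lambda d: d["kind"] == kind]
                    .set_index("feature")["log2fc"]
                for s in tables
            })
            discordance[(t, kind)] = discordant_events(list(common["feature"]), fc_ctrl)
    all_specific = pd.concat(
        [tab for tab in specific.values() if len(tab)], ignore_index=True
    ) if any(len(t) for t in specific.values()) else pd.DataFrame(columns=["feature"])
    sio.write_tsv(all_specific, out / "subtype_specific_features.tsv", index=False)

    # -------------------------------------------------------------- clinical
    stage("clinical")
    clinical_report: dict = {}
    if cohort.clinical is not None and len(cohort.clinical):
        combined = combined_score(cohort.clinical)
        deg_lists = {
            (s, t): list(specific[(t, s, "gene")]["feature"])
            for t in cell_types for s in range(1, assignment.k + 1)
        }
        fc_matrices = {}
        for t in cell_types:
            genes_needed = sorted({g for (s, tt), gl in deg_lists.items() if tt == t for g in gl})
            if not genes_needed:
                fc_matrices[t] = pd.DataFrame(index=case_ids)
                continue
            e = expr[t]
            ctrl = (e.cells["diagnosis"] == "control").to_numpy()
            fc_matrices[t] = pd.DataFrame({
                p: individual_fold_changes(e, p, ctrl, genes_needed) for p in case_ids
            }).T
        meta = meta_correlation_report(deg_lists, fc_matrices, combined, config.clinical)
        ttests = category_rank_ttests(cohort.clinical, assignment)
        clinical_report = {"combined": combined, "meta": meta, "ttests": ttests,
                           "fc_matrices": fc_matrices}
        sio.write_tsv(meta, out / "clinical_meta.tsv", index=False)
        sio.write_tsv(ttests, out / "clinical_ttests.tsv", index=False)
        if config.risk_genes:
            enr_rows = []
            universe = list(cohort.gene_ids)
            for (s, t), gl in deg_lists.items():
                if len(gl) < config.clinical.min_degs:
                    continue
                res = hypergeom_enrichment(gl, config.risk_genes, universe)
                enr_rows.append({"subtype": s, "cell_type": t, **res})
            enr = pd.DataFrame(enr_rows)
            if len(enr):
                from statsmodels.stats.multitest import multipletests
                enr["fdr"] = np.nan
                for s in enr["subtype"].unique():
                    m = enr["subtype"] == s
                    enr.loc[m, "fdr"] = multipletests(enr.loc[m, "p"], method="fdr_bh")[1]
            clinical_report["risk_enrichment"] = enr
            sio.write_tsv(enr, out / "risk_enrichment.tsv", index=False)
    else:
        logger.warning("clinical table missing; clinical stage skipped")
        manifest["stages"][-1] = "clinical(skipped)"

    # ------------------------------------------------------------ validation
    stage("validation")
    validation_report: dict = {}
    if config.bulk is not None:
        validation_report = run_bulk_correspondence(
            config.bulk, expr, assignment, cohort, config
        )
        sio.write_tsv(validation_report["r"], out / "correspondence_r.tsv")
        sio.write_tsv(validation_report["p"], out / "correspondence_p.tsv")
    else:
        manifest["stages"][-1] = "validation(skipped)"

    # ------------------------------------------------------------ prediction
    stage("prediction")
    prediction_reports: list = []
    if config.with_prediction:
        pred_types = config.prediction_cell_types or tuple(cell_types)
        for t in pred_types:
            feats = sorted({
                f for s in range(1, assignment.k + 1)
                for f in specific[(t, s, "gene")]["feature"]
            })
            if len(feats) < config.clinical.min_degs:
                logger.warning("cell type %s has %d subtype-specific genes; prediction skipped",
                               t, len(feats))
                continue
            e = expr[t]
            case_cells = e.cells.index[e.cells["diagnosis"] == "case"]
            X = e.values.loc[feats, case_cells].T
            lab = e.cells.loc[case_cells, "patient_id"].map(subtype_of)
            pat = e.cells.loc[case_cells, "patient_id"]
            for scheme, folds in (("random_cells", 10), ("leave_patient_out", 10)):
                params = PredictionParams(scheme=scheme, cv_folds=folds,
                                          cv_repeats=config.cv_repeats,
                                          component_grid=config.component_grid,
                                          seed=config.seed + 7)
                rep = run_prediction(X, lab, pat, subtype_of, params)
                rep["cell_type"] = t
                prediction_reports.append(rep)
            prof = X.groupby(pat).mean()
            params = PredictionParams(scheme="patient_level", cv_folds=3,
                                      cv_repeats=config.cv_repeats,
                                      component_grid=config.component_grid,
                                      seed=config.seed + 7)
            lab_pat = pd.Series({p: subtype_of[p] for p in prof.index})
            rep = run_prediction(prof, lab_pat, pd.Series(prof.index, index=prof.index),
                                 subtype_of, params)
            rep["cell_type"] = t
            prediction_reports.append(rep)
        sio.write_json(prediction_reports, out / "prediction.json")

    manifest["n_stages"] = len(manifest["stages"])
    sio.write_json(manifest, out / "manifest.json")
    return PipelineResult(expr, scores, fused_gene, fused_set, fused_final,
                          assignment, modality_assignments, de_tables, specific,
                          unique_common, discordance, clinical_report,
                          validation_report, prediction_reports, manifest)


def run_bulk_correspondence(bulk: pd.DataFrame, expr, assignment, cohort, config) -> dict:
    """Derive subtypes on a bulk patients x genes matrix with the same
    GSVA + SNF machinery (genes and gene sets as the two views) and
    correlate fold-change signatures with the single-nucleus subtypes."""
    case_ids = [p for p in bulk.index if p in assignment.labels.index]
    bulk_cases = bulk.loc[case_ids]
    genes_frame = bulk_cases.T            # genes x patients
    genes_frame = genes_frame.loc[genes_frame.std(axis=1) > 0]
    set_scores = gsva_scores(genes_frame, cohort.gene_sets, config.gsva)

    snf_params = config.snf
    views = []
    for frame in (genes_frame.T, set_scores.T):
        d = squared_euclidean_distances(frame, standardize=snf_params.standardize)
        views.append(affinity_matrix(d, K=snf_params.K, mu=snf_params.mu, kernel=snf_params.kernel))
    fused = snf_fuse(views, snf_params)
    k_eig, _, _ = estimate_n_clusters(fused, snf_params.k_range)
    k = config.fixed_k if config.fixed_k is not None else k_eig
    bulk_assign = spectral_cluster(fused, k, seed=snf_params.seed)

    # single-nucleus fold changes: cells combined across all cell types per individual
    combined_expr = _concat_expr(expr)
    fc_sn = subtype_fold_changes(combined_expr, assignment, combine_cell_types=True)
    fc_bulk = subtype_fold_changes(bulk_cases, bulk_assign)
    r, p = correspondence_matrix(fc_sn, fc_bulk)
    return {"bulk_assignment": bulk_assign, "r": r, "p": p, "pairing": match_subtypes(r),
            "fc_sn": fc_sn, "fc_bulk": fc_bulk, "k_bulk": k}


def _concat_expr(expr: dict[str, CellExpressionMatrix]) -> CellExpressionMatrix:
    types = sorted(expr)
    values = pd.concat([expr[t].values for t in types], axis=1)
    cells = pd.concat([expr[t].cells for t in types], axis=0)
    return CellExpressionMatrix(values, cells, expr[types[0]].patients)


def _sig(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    sig = table[(table["kind"] == kind) & table["significant"]]
    return sig.drop(columns="significant").reset_index(drop=True)
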