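"""Seeded synthetic single-nucleus cohorts with planted subtype structure.

The generator emulates the statistical shape of a multi-patient,
multi-cell-type snRNA-seq case/control cohort: negative-binomial counts
with logit-linear dropout, per-cell library-size variation, nuisance
batch/region structure, three planted patient subtypes with
subtype-by-cell-type differential genes of known signed log2 effect,
gene sets whose members shift coordinately, and clinical category
scores linked to each patient's realized effect magnitude. Ground truth
is returned alongside the data so every downstream stage can be scored
against what was planted.

Counts for gene g, cell c of patient p in cell type t are drawn as

    NB(mean = b_g * m_tg * u_bg * v_rg * 2^(s * fc * sev_p) * L_c,
       dispersion = phi)

with b_g a log-normal baseline, m_tg / u_bg / v_rg mild cell-type /
batch / region multipliers, L_c the cell's library factor, and the
2^(...) term present only for planted (subtype, cell type, gene)
triples. A Bernoulli keep with logit linear in the log mean thins the
counts, producing MAST-style zero inflation. Patient severities sev_p
are log-normal, normalized to mean 1 within each subtype so the
group-level log2 fold change stays exactly +/- fc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as sio

DEFAULT_CELL_TYPES = ["ExN", "InN", "AST"]
CLINICAL_CATEGORIES = ["A", "B_verbal", "B_nonverbal", "C", "D"]
_CLINICAL_BASE = {"A": 14.0, "B_verbal": 10.0, "B_nonverbal": 8.0, "C": 5.0, "D": 3.0}
_CLINICAL_SLOPE = 8.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the pipeline targets: 15 case
    patients in three subtypes of 6/4/5, 16 controls, three cell types,
    and planted per-(subtype, cell type) differential genes with
    |log2FC| = 1.
    """

    seed: int = 0
    n_subtypes: int = 3
    patients_per_subtype: list[int] = field(default_factory=lambda: [6, 4, 5])
    n_controls: int = 16
    cell_types: list[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    cells_per_patient_per_type: int = 100
    n_genes: int = 500
    n_gene_sets: int = 50
    genes_per_set: tuple[int, int] = (10, 40)
    de_genes_per_subtype_per_type: int = 30
    de_log2fc: float = 1.0
    set_shift_fraction: float = 0.8
    shifted_sets_per_pair: int = 2
    nb_dispersion: float = 0.4
    # keep probability stays near 1 over the expressed stratum so the
    # thinning adds zeros without distorting group mean ratios much
    dropout_logit_slope: float = 1.0
    dropout_logit_intercept: float = 3.0
    base_mean_log_mu: float = 0.0  # median 1 count/cell: the HVG stratum
    base_mean_log_sd: float = 1.2
    library_log_sd: float = 0.3
    celltype_effect_sd: float = 0.5
    batch_effect_sd: float = 0.05
    region_effect_sd: float = 0.05
    n_batches: int = 4
    severity_sd: float = 0.15
    clinical_noise_sd: float = 1.0
    clinical_linkage: float = 1.0
    active_subtypes: list[int] | None = None
    bulk_noise_sd: float = 0.1
    # planted DE genes are drawn from the stratum detectably expressed
    # in the target cell type: a gene averaging well below ~1 count/cell
    # is mostly zeros and carries no recoverable fold change on the
    # log-normalized scale
    de_min_base_mean: float = 1.0

    def validate(self) -> "SimConfig":
        if len(self.patients_per_subtype) != self.n_subtypes:
            raise ValueError(
                f"patients_per_subtype has length {len(self.patients_per_subtype)}, "
                f"expected n_subtypes={self.n_subtypes}"
            )
        positive = {
            "n_controls": self.n_controls,
            "cells_per_patient_per_type": self.cells_per_patient_per_type,
            "n_genes": self.n_genes,
            "n_gene_sets": self.n_gene_sets,
            "nb_dispersion": self.nb_dispersion,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if any(n <= 0 for n in self.patients_per_subtype):
            raise ValueError("patients_per_subtype entries must be positive")
        if self.de_genes_per_subtype_per_type > self.n_genes:
            raise ValueError("de_genes_per_subtype_per_type exceeds n_genes")
        n_pairs = len(self.active_subtype_indices()) * len(self.cell_types)
        if self.de_genes_per_subtype_per_type * n_pairs > self.n_genes:
            raise ValueError(
                "not enough genes for disjoint planted DE sets: "
                f"{self.de_genes_per_subtype_per_type} x {n_pairs} > {self.n_genes}"
            )
        if not (0.0 <= self.set_shift_fraction <= 1.0):
            raise ValueError("set_shift_fraction must be in [0, 1]")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be nonnegative")
        return self

    def active_subtype_indices(self) -> list[int]:
        if self.active_subtypes is None:
            return list(range(self.n_subtypes))
        bad = [s for s in self.active_subtypes if not 0 <= s < self.n_subtypes]
        if bad:
            raise ValueError(f"active_subtypes out of range: {bad}")
        return sorted(set(self.active_subtypes))


@dataclass
class SyntheticTruth:
    """Planted ground truth for a simulated cohort."""

    subtype_of_patient: dict[str, int]                    # case patient -> 1..k
    de_features: dict[tuple[int, str], list[tuple[str, float]]]
    shifted_sets: dict[tuple[int, str], list[tuple[str, float]]]
    clinical_scores: pd.DataFrame
    covariates: dict
    severity: dict[str, float]                            # case patient -> sev_p
    planted_means: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "subtype_of_patient": self.subtype_of_patient,
            "de_features": {
                f"{s}|{t}": [[g, float(e)] for g, e in feats]
                for (s, t), feats in self.de_features.items()
            },
            "shifted_sets": {
                f"{s}|{t}": [[name, float(e)] for name, e in sets]
                for (s, t), sets in self.shifted_sets.items()
            },
            "clinical_scores": self.clinical_scores.to_dict(orient="index"),
            "covariates": self.covariates,
            "severity": self.severity,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        def unkey(mapping):
            out = {}
            for key, items in mapping.items():
                s, t = key.split("|", 1)
                out[(int(s), t)] = [(name, float(e)) for name, e in items]
            return out

        clinical = pd.DataFrame.from_dict(d["clinical_scores"], orient="index")
        clinical.index.name = "patient_id"
        return cls(
            subtype_of_patient={p: int(s) for p, s in d["subtype_of_patient"].items()},
            de_features=unkey(d["de_features"]),
            shifted_sets=unkey(d["shifted_sets"]),
            clinical_scores=clinical[CLINICAL_CATEGORIES],
            covariates=d["covariates"],
            severity={p: float(v) for p, v in d["severity"].items()},
        )


@dataclass
class Cohort:
    """Everything simulate_cohort produces, ready for write_cohort."""

    counts: dict[str, sp.csr_matrix]      # cell type -> genes x cells
    gene_ids: list[str]
    cells: pd.DataFrame                   # all cells, indexed by cell_id
    patients: pd.DataFrame
    gene_sets: dict[str, list[str]]
    clinical: pd.DataFrame
    truth: SyntheticTruth

    def cells_of(self, cell_type: str) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"] == cell_type]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a full synthetic cohort; byte-deterministic under (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    cell_types = list(config.cell_types)

    patients, subtype_of = _draw_patients(config, rng)
    severity = _draw_severity(config, subtype_of, rng)
    base_mean = np.exp(rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, config.n_genes))
    base_mean = np.clip(base_mean, 1e-3, 50.0)
    ct_mult = {
        t: np.exp(rng.normal(0.0, config.celltype_effect_sd, config.n_genes)) for t in cell_types
    }
    batch_ids = [f"B{i+1}" for i in range(config.n_batches)]
    batch_mult = {b: np.exp(rng.normal(0.0, config.batch_effect_sd, config.n_genes)) for b in batch_ids}
    region_mult = {r: np.exp(rng.normal(0.0, config.region_effect_sd, config.n_genes)) for r in ("ACC", "PFC")}

    de_features = _plant_de(config, genes, base_mean, ct_mult, rng)
    gene_sets, descriptions, shifted_sets = _build_gene_sets(config, genes, de_features, rng)

    counts: dict[str, sp.csr_matrix] = {}
    cell_frames = []
    planted_means: dict[str, pd.DataFrame] = {}
    for t in cell_types:
        mat, cell_meta, pat_means = _simulate_cell_type(
            config, rng, t, genes, patients, subtype_of, severity,
            base_mean * ct_mult[t], batch_mult, region_mult, de_features,
        )
        counts[t] = mat
        cell_frames.append(cell_meta)
        planted_means[t] = pat_means
    cells = pd.concat(cell_frames)

    clinical = _draw_clinical(config, subtype_of, severity, de_features, rng)
    truth = SyntheticTruth(
        subtype_of_patient={p: s + 1 for p, s in subtype_of.items()},
        de_features=de_features,
        shifted_sets=shifted_sets,
        clinical_scores=clinical,
        covariates={
            "patients": patients.to_dict(orient="index"),
            "cells": {"columns": ["batch", "ribo_fraction"]},
        },
        severity=severity,
        planted_means=planted_means,
    )
    return Cohort(counts, genes, cells, patients, gene_sets, clinical, truth)


def _draw_patients(config: SimConfig, rng) -> tuple[pd.DataFrame, dict[str, int]]:
    rows = []
    subtype_of = {}
    idx = 0
    for s, n in enumerate(config.patients_per_subtype):
        for _ in range(n):
            idx += 1
            pid = f"P{idx:02d}"
            subtype_of[pid] = s
            rows.append((pid, "case"))
    for i in range(config.n_controls):
        rows.append((f"C{i+1:02d}", "control"))
    pids = [r[0] for r in rows]
    patients = pd.DataFrame(
        {
            "diagnosis": [r[1] for r in rows],
            "age": rng.integers(4, 23, len(rows)),
            "sex": rng.choice(["M", "F"], len(rows)),
            "RIN": np.round(np.clip(rng.normal(7.5, 0.8, len(rows)), 5.0, 10.0), 2),
            "PMI": np.round(np.clip(rng.normal(20.0, 6.0, len(rows)), 5.0, 40.0), 1),
            "region": rng.choice(["ACC", "PFC"], len(rows)),
            "batch": rng.choice([f"B{i+1}" for i in range(config.n_batches)], len(rows)),
        },
        index=pd.Index(pids, name="patient_id"),
    )
    return patients, subtype_of


def _draw_severity(config, subtype_of, rng) -> dict[str, float]:
    raw = {p: float(np.exp(rng.normal(0.0, config.severity_sd))) for p in subtype_of}
    sev = {}
    for s in range(config.n_subtypes):
        members = [p for p, g in subtype_of.items() if g == s]
        mean = np.mean([raw[p] for p in members])
        for p in members:
            sev[p] = raw[p] / mean
    return sev


def _plant_de(config, genes, base_mean, ct_mult, rng) -> dict[tuple[int, str], list[tuple[str, float]]]:
    active = config.active_subtype_indices()
    m = config.de_genes_per_subtype_per_type
    de: dict[tuple[int, str], list[tuple[str, float]]] = {}
    used: set[str] = set()
    for s in active:
        for t in config.cell_types:
            mean_t = base_mean * ct_mult[t]
            eligible = [g for g, mu in zip(genes, mean_t)
                        if mu >= config.de_min_base_mean and g not in used]
            if len(eligible) < m:
                raise ValueError(
                    f"only {len(eligible)} unused genes reach de_min_base_mean="
                    f"{config.de_min_base_mean} in cell type {t}; need {m}"
                )
            chosen = list(rng.choice(eligible, m, replace=False))
            used.update(chosen)
            signs = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
            de[(s, t)] = [(g, float(sg * config.de_log2fc)) for g, sg in zip(chosen, signs)]
    return de


def _build_gene_sets(config, genes, de_features, rng):
    """Gene sets: `shifted_sets_per_pair` sets per planted (subtype, cell
    type) take set_shift_fraction of members from that pair's same-sign
    DE genes (a coordinated shift); the remainder are random."""
    lo, hi = config.genes_per_set
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    shifted: dict[tuple[int, str], list[tuple[str, float]]] = {}
    idx = 0
    for (s, t), feats in de_features.items():
        shifted[(s, t)] = []
        for j in range(config.shifted_sets_per_pair):
            if idx >= config.n_gene_sets:
                break
            sign = 1.0 if j % 2 == 0 else -1.0
            # planted signs alternate by position, so parity identifies
            # the same-sign genes even when de_log2fc is 0
            signed = [g for i, (g, _e) in enumerate(feats)
                      if (1.0 if i % 2 == 0 else -1.0) == sign]
            n_from_de = max(1, min(len(signed), int(round(config.set_shift_fraction * lo))))
            size = max(lo, int(np.ceil(n_from_de / max(config.set_shift_fraction, 1e-12))))
            size = min(size, hi)
            members = list(rng.choice(signed, n_from_de, replace=False))
            others = [g for g in genes if g not in members]
            members += list(rng.choice(others, size - n_from_de, replace=False))
            name = f"SET{idx:03d}"
            sets[name] = members
            descriptions[name] = f"planted shift subtype {s + 1} {t}"
            shifted[(s, t)].append((name, float(sign * config.de_log2fc)))
            idx += 1
    while idx < config.n_gene_sets:
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{idx:03d}"
        sets[name] = list(rng.choice(genes, size, replace=False))
        descriptions[name] = "random"
        idx += 1
    sets = {name: sets[name] for name in sorted(sets)}
    return sets, descriptions, shifted


def _simulate_cell_type(config, rng, cell_type, genes, patients, subtype_of,
                        severity, gene_mean, batch_mult, region_mult, de_features):
    n_genes = len(genes)
    n_cells_pp = config.cells_per_patient_per_type
    fc_idx = {g: i for i, g in enumerate(genes)}

    blocks = []
    cell_rows = []
    pat_mean_rows = {}
    for pid, prow in patients.iterrows():
        mean_pg = gene_mean * batch_mult[prow["batch"]] * region_mult[prow["region"]]
        if prow["diagnosis"] == "case":
            s = subtype_of[pid]
            if (s, cell_type) in de_features:
                mult = np.ones(n_genes)
                sev = severity[pid]
                for g, eff in de_features[(s, cell_type)]:
                    mult[fc_idx[g]] = 2.0 ** (eff * sev)
                mean_pg = mean_pg * mult
        pat_mean_rows[pid] = mean_pg

        lib = np.exp(rng.normal(0.0, config.library_log_sd, n_cells_pp))
        mean_cg = mean_pg[:, None] * lib[None, :]
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean_cg))
        logit = config.dropout_logit_intercept + config.dropout_logit_slope * np.log(mean_cg)
        p_keep = 1.0 / (1.0 + np.exp(-logit))
        keep = rng.random(mean_cg.shape) < p_keep
        counts = counts * keep

        cell_ids = [f"{pid}_{cell_type}_{i:03d}" for i in range(n_cells_pp)]
        blocks.append(sp.csr_matrix(counts))
        cell_rows.append(pd.DataFrame(
            {
                "patient_id": pid,
                "diagnosis": prow["diagnosis"],
                "cell_type": cell_type,
                "region": prow["region"],
                "batch": prow["batch"],
                "ribo_fraction": np.round(rng.beta(2.0, 18.0, n_cells_pp), 4),
            },
            index=pd.Index(cell_ids, name="cell_id"),
        ))
    mat = sp.hstack(blocks, format="csr")
    cells = pd.concat(cell_rows)
    pat_means = pd.DataFrame(pat_mean_rows, index=genes).T
    pat_means.index.name = "patient_id"
    return mat, cells, pat_means


def _draw_clinical(config, subtype_of, severity, de_features, rng) -> pd.DataFrame:
    """ADI-R-like category scores linked to each case patient's mean
    planted |effect|; integer scales, clipped at zero."""
    rows = {}
    for pid, s in subtype_of.items():
        pair_effects = [
            abs(e) for (ss, _t), feats in de_features.items() if ss == s for _g, e in feats
        ]
        sigma = severity[pid] * float(np.mean(pair_effects)) if pair_effects else 0.0
        scores = {}
        for cat in CLINICAL_CATEGORIES:
            raw = (_CLINICAL_BASE[cat]
                   + _CLINICAL_SLOPE * config.clinical_linkage * sigma
                   + rng.normal(0.0, config.clinical_noise_sd))
            scores[cat] = int(max(0, round(raw)))
        rows[pid] = scores
    df = pd.DataFrame.from_dict(rows, orient="index")[CLINICAL_CATEGORIES]
    df.index.name = "patient_id"
    return df


def simulate_bulk(config: SimConfig, truth: SyntheticTruth,
                  weights: dict[str, float] | None = None,
                  seed_offset: int = 104729) -> pd.DataFrame:
    """Pseudo-bulk patients x genes log2 expression sharing the cohort's
    planted subtype effects, collapsed across cell types.

    Each patient's profile is the cell-type-weighted mixture of that
    patient's planted per-cell-type mean profiles, log2(x+1)
    transformed, plus Gaussian noise of sd `bulk_noise_sd`.
    """
    if not truth.planted_means:
        raise ValueError("truth has no planted means; pass the truth returned by simulate_cohort")
    rng = np.random.default_rng(config.seed + seed_offset)
    cell_types = list(truth.planted_means)
    if weights is None:
        weights = {t: 1.0 / len(cell_types) for t in cell_types}
    total = sum(weights.values())
    mix = sum(truth.planted_means[t] * (weights[t] / total) for t in cell_types)
    values = np.log2(mix + 1.0)
    if config.bulk_noise_sd > 0:
        values = values + rng.normal(0.0, config.bulk_noise_sd, values.shape)
    return values


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to disk in the pipeline's input formats.

    Per cell type: <ct>.mtx (genes x cells, integer counts),
    <ct>.genes.tsv, <ct>.cells.tsv. Plus patients.tsv, sets.gmt,
    clinical.tsv, truth.json.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, mat in cohort.counts.items():
        cells_t = cohort.cells_of(t)
        sio.write_mtx(out / f"{t}.mtx", mat)
        sio.write_tsv(pd.DataFrame({"gene_id": cohort.gene_ids}), out / f"{t}.genes.tsv", index=False)
        sio.write_tsv(cells_t, out / f"{t}.cells.tsv")
    sio.write_tsv(cohort.patients, out / "patients.tsv")
    sio.write_gmt(cohort.gene_sets, out / "sets.gmt")
    sio.write_tsv(cohort.clinical, out / "clinical.tsv")
    sio.write_json(cohort.truth.to_json_dict(), out / "truth.json")


def read_cohort(in_dir) -> Cohort:
    """Read back a cohort written by write_cohort (lossless round-trip
    for counts, metadata, sets, clinical scores, and JSON-able truth)."""
    from pathlib import Path

    src = Path(in_dir)
    patients = sio.read_tsv(src / "patients.tsv")
    truth = SyntheticTruth.from_json_dict(sio.read_json(src / "truth.json"))
    gene_sets = sio.read_gmt(src / "sets.gmt")
    clinical = sio.read_clinical(src / "clinical.tsv")
    counts = {}
    cell_frames = []
    gene_ids: list[str] = []
    for mtx in sorted(src.glob("*.mtx")):
        t = mtx.stem
        counts[t] = sio.read_mtx(mtx)
        genes_t = list(sio.read_tsv(src / f"{t}.genes.tsv", index_col=None)["gene_id"])
        if gene_ids and genes_t != gene_ids:
            raise ValueError(f"gene order mismatch between cell types in {src}")
        gene_ids = genes_t
        cell_frames.append(sio.read_tsv(src / f"{t}.cells.tsv"))
    cells = pd.concat(cell_frames)
    return Cohort(counts, gene_ids, cells, patients, gene_sets, clinical, truth)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["genes_per_set"] = list(d["genes_per_set"])
    return d
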