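import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snsubtype.clinical import (ClinicalParams, category_rank_ttests,
                                combined_score, fisher_meta,
                                gene_clinical_correlation,
                                hypergeom_enrichment,
                                individual_fold_changes,
                                meta_correlation_report)
from snsubtype.containers import SubtypeAssignment
from tests.oracles import hypergeom_enrichment_oracle


def test_combined_score_hand_examples():
    raw = pd.DataFrame({"A": [1, 2, 3], "C": [3, 2, 1]},
                       index=["p1", "p2", "p3"])
    combined = combined_score(raw)
    assert np.allclose(combined, [2.0, 2.0, 2.0])

    one_cat = combined_score(pd.DataFrame({"A": [5, 1, 3]}, index=["p1", "p2", "p3"]))
    assert list(one_cat) == [3.0, 1.0, 2.0]

    tied = combined_score(pd.DataFrame({"A": [4, 4, 4, 4]}, index=list("abcd")))
    assert np.allclose(tied, 2.5)  # (n+1)/2 average rank


def test_combined_score_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.integers(0, 30, size=(8, 3)).astype(float),
                       columns=["A", "C", "D"], index=[f"p{i}" for i in range(8)])
    base = combined_score(raw)
    warped = raw.copy()
    warped["A"] = np.exp(warped["A"] / 10.0)
    warped["C"] = warped["C"] ** 3
    assert np.allclose(base, combined_score(warped))


def test_combined_score_drops_all_missing_patient():
    raw = pd.DataFrame({"A": [1.0, np.nan], "C": [2.0, np.nan]}, index=["p1", "p2"])
    combined = combined_score(raw)
    assert list(combined.index) == ["p1"]


def test_fisher_meta_exact_cases():
    assert fisher_meta([0.37]) == pytest.approx(0.37, abs=1e-12)
    assert fisher_meta([1.0, 1.0, 1.0]) == pytest.approx(1.0)
    x = -2 * np.log([0.05, 0.05]).sum()
    assert fisher_meta([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x, 4), abs=1e-12)
    assert fisher_meta([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-4)
    with pytest.raises(ValueError):
        fisher_meta([1.2])
    with pytest.raises(ValueError):
        fisher_meta([])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8), st.integers(0, 7))
def test_fisher_meta_exchangeable_and_monotone(pvals, idx):
    base = fisher_meta(pvals)
    assert base == pytest.approx(fisher_meta(list(reversed(pvals))), rel=1e-12)
    idx = idx % len(pvals)
    smaller = list(pvals)
    smaller[idx] = smaller[idx] / 2.0
    assert fisher_meta(smaller) <= base + 1e-15


def test_hypergeom_trivial_cases():
    universe = [f"g{i}" for i in range(10)]
    res = hypergeom_enrichment(universe[:5], universe[8:], universe)
    assert res["overlap"] == 0
    # P(X >= 0) = 1
    none = hypergeom_enrichment(universe[:3], [], universe)
    assert none["p"] == 1.0
    full = hypergeom_enrichment(universe[:5], universe, universe)
    assert full["overlap"] == 5 and full["p"] == 1.0
    with pytest.raises(ValueError):
        hypergeom_enrichment([], [], [])


def test_hypergeom_matches_exact_enumeration_small_universes():
    """p equals brute-force enumeration for every configuration with
    |universe| <= 12."""
    worked = 0
    for M in (5, 7, 9, 12):
        universe = [f"g{i}" for i in range(M)]
        for n_ref in range(0, M + 1, 2):
            for n_query in range(1, M + 1, 2):
                for offset in range(0, M - n_query + 1, 3):
                    query = set(universe[offset:offset + n_query])
                    reference = set(universe[:n_ref])
                    res = hypergeom_enrichment(query, reference, universe)
                    _obs, p_oracle = hypergeom_enrichment_oracle(query, reference, universe)
                    assert res["p"] == pytest.approx(p_oracle, abs=1e-12)
                    worked += 1
    assert worked > 50


def test_hypergeom_worked_example():
    # universe 10, reference 4, query 5, overlap 3 -> p = 66/252
    universe = [f"g{i}" for i in range(10)]
    reference = universe[:4]
    query = universe[1:4] + universe[8:]
    res = hypergeom_enrichment(query, reference, universe)
    assert res["overlap"] == 3
    assert res["p"] == pytest.approx(66 / 252, abs=1e-12)


def test_gene_clinical_correlation_cases():
    fc = pd.DataFrame({"g1": [1.0, 2.0, 3.0, 4.0], "g2": [1.0, 1.0, 1.0, 1.0]},
                      index=["p1", "p2", "p3", "p4"])
    score = pd.Series([4.0, 3.0, 2.0, 1.0], index=fc.index)
    out = gene_clinical_correlation(fc, score)
    assert out.loc["g1", "r"] == pytest.approx(-1.0)
    assert out.loc["g1", "p"] < 0.01
    assert "g2" not in out.index  # zero variance excluded
    prop = pd.Series([2.0, 4.0, 6.0, 8.0], index=fc.index)
    assert gene_clinical_correlation(fc[["g1"]], prop).loc["g1", "r"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match=">= 3"):
        gene_clinical_correlation(fc.iloc[:2], score.iloc[:2])


def _assignment(labels: dict) -> SubtypeAssignment:
    s = pd.Series(labels, name="subtype")
    return SubtypeAssignment(s, k=len(set(labels.values())))


def test_category_ttests_extreme_separation_and_bh():
    rng = np.random.default_rng(1)
    patients = [f"p{i}" for i in range(12)]
    clin = pd.DataFrame(rng.integers(5, 25, size=(12, 5)).astype(float),
                        columns=["A", "B_verbal", "B_nonverbal", "C", "D"], index=patients)
    clin.loc[patients[:4], "C"] = [1, 2, 3, 4]       # subtype 1 gets the lowest C ranks
    labels = {p: (1 if i < 4 else 2) for i, p in enumerate(patients)}
    table = category_rank_ttests(clin, _assignment(labels))
    sub1 = table[table["subtype"] == 1].set_index("category")
    assert sub1["p"].idxmin() == "C"
    assert (sub1["fdr"] >= sub1["p"] - 1e-12).all()


def test_bh_step_up_worked_example():
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests([0.01, 0.02, 0.03, 0.04, 0.05], method="fdr_bh")[1]
    assert np.allclose(fdr, 0.05)


def test_category_ttests_permutation_null_rate():
    rng = np.random.default_rng(2)
    patients = [f"p{i}" for i in range(15)]
    below = total = 0
    for _ in range(200):
        clin = pd.DataFrame(rng.normal(10, 3, size=(15, 5)),
                            columns=["A", "B_verbal", "B_nonverbal", "C", "D"],
                            index=patients)
        labels = dict(zip(patients, rng.permutation([1] * 6 + [2] * 4 + [3] * 5)))
        table = category_rank_ttests(clin, _assignment(labels))
        below += (table["p"] < 0.05).sum()
        total += table["p"].notna().sum()
    assert 0.02 <= below / total <= 0.08


def test_individual_fold_changes_null_and_planted(small_cohort):
    from snsubtype.preprocess import normalize_log

    _cfg, co = small_cohort
    t = "ExN"
    e = normalize_log(co.counts[t], co.gene_ids, co.cells_of(t), co.patients)
    ctrl = (e.cells["diagnosis"] == "control").to_numpy()
    feats = co.truth.de_features[(0, t)]
    genes = [g for g, _ in feats]
    up_genes = [g for g, eff in feats if eff > 0]
    sub1_patients = [p for p, s in co.truth.subtype_of_patient.items() if s == 1]
    other_patients = [p for p, s in co.truth.subtype_of_patient.items() if s != 1]
    fc_in = individual_fold_changes(e, sub1_patients[0], ctrl, genes)
    fc_out = individual_fold_changes(e, other_patients[0], ctrl, genes)
    assert len(fc_in) == len(genes)
    assert fc_in[up_genes].mean() > 0.5
    assert abs(fc_out[genes].mean()) < 0.25
    with pytest.raises(ValueError, match="control"):
        individual_fold_changes(e, sub1_patients[0], np.zeros(len(e.cells), bool), genes)


def test_meta_report_null_not_strongly_enriched():
    """With clinical_linkage = 0 the meta p-values are not enriched
    below 0.1 by more than 10 percentage points over the nominal rate
    (per-gene correlation p-values within a subtype are positively
    dependent, which inflates the Fisher tail somewhat; the check
    bounds that inflation)."""
    import logging

    from snsubtype.preprocess import normalize_log
    from snsubtype.synthetic import SimConfig, simulate_cohort

    logging.disable(logging.WARNING)
    below = total = 0
    for seed in range(40, 60):
        cfg = SimConfig(seed=seed, clinical_linkage=0.0, n_genes=350,
                        de_genes_per_subtype_per_type=12,
                        cells_per_patient_per_type=50, n_gene_sets=10)
        co = simulate_cohort(cfg)
        combined = combined_score(co.clinical)
        cases = list(co.truth.subtype_of_patient)
        deg_lists = {(s + 1, t): [g for g, _ in co.truth.de_features[(s, t)]]
                     for s in range(3) for t in cfg.cell_types}
        fcm = {}
        for t in cfg.cell_types:
            e = normalize_log(co.counts[t], co.gene_ids, co.cells_of(t), co.patients)
            ctrl = (e.cells["diagnosis"] == "control").to_numpy()
            genes = sorted({g for (s, tt), gl in deg_lists.items() if tt == t for g in gl})
            fcm[t] = pd.DataFrame({p: individual_fold_changes(e, p, ctrl, genes)
                                   for p in cases}).T
        report = meta_correlation_report(deg_lists, fcm, combined, ClinicalParams())
        ok = report["meta_p"].notna()
        below += (report.loc[ok, "meta_p"] < 0.1).sum()
        total += int(ok.sum())
    assert total >= 150
    assert below / total <= 0.20


def test_meta_report_filters_and_planted_signal():
    """The planted-effect subtype reaches meta_p < 0.1; feature lists
    below the size floor are reported NA."""
    import logging

    from snsubtype.preprocess import normalize_log
    from snsubtype.synthetic import SimConfig, simulate_cohort

    logging.disable(logging.WARNING)
    cfg = SimConfig(seed=31, active_subtypes=[0], cell_types=["ExN"],
                    cells_per_patient_per_type=60, n_genes=300,
                    de_genes_per_subtype_per_type=20, n_gene_sets=10)
    co = simulate_cohort(cfg)
    e = normalize_log(co.counts["ExN"], co.gene_ids, co.cells_of("ExN"), co.patients)
    ctrl = (e.cells["diagnosis"] == "control").to_numpy()
    combined = combined_score(co.clinical)
    genes = [g for g, _ in co.truth.de_features[(0, "ExN")]]
    cases = list(co.truth.subtype_of_patient)
    fcm = {"ExN": pd.DataFrame({p: individual_fold_changes(e, p, ctrl, genes)
                                for p in cases}).T}
    deg_lists = {(1, "ExN"): genes, (2, "ExN"): genes[:4], (3, "ExN"): genes[:7]}
    report = meta_correlation_report(deg_lists, fcm, combined, ClinicalParams(),
                                     small_filter_subtypes={3})
    report = report.set_index("subtype")
    assert report.loc[1, "meta_p"] < 0.1 and report.loc[1, "significant"]
    assert report.loc[2, "note"] == "NA_below_min_degs"      # 4 < 10
    assert report.loc[3, "note"] == ""                        # 7 >= relaxed floor 5
    assert np.isnan(report.loc[2, "meta_p"])
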