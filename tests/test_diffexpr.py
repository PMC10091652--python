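import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from snsubtype.diffexpr import (DEThresholds, build_design, de_features,
                                discordant_events, fit_fdist, hurdle_lrt,
                                moderated_lm, partition_unique_common,
                                subtype_specific, trigamma_inverse)
from tests.oracles import ebayes_oracle, gaussian_two_sample_lrt


def _null_y(rng, n=200, detect=0.7):
    return np.maximum(rng.normal(1.0, 1.0, n), 0.0) * (rng.random(n) < detect)


def test_identical_designs_give_null_result(rng):
    y = _null_y(rng)
    design = np.column_stack([np.ones(200), rng.random(200)])
    res = hurdle_lrt(y, design, design)
    assert res["stat"] == 0.0 and res["p"] == 1.0


def test_all_zero_gene_is_flagged():
    design = np.ones((50, 1))
    res = hurdle_lrt(np.zeros(50), np.column_stack([design, np.arange(50) < 25]), design)
    assert res["p"] == 1.0 and res["log2fc"] == 0.0 and "all_zero" in res["flags"]


def test_all_expressed_matches_classical_gaussian_lrt(rng):
    """When every cell expresses the gene, the hurdle reduces to the
    two-sample Gaussian LRT with one degree of freedom."""
    y1 = rng.normal(2.0, 1.0, 60) + 5
    y0 = rng.normal(1.5, 1.0, 70) + 5
    y = np.concatenate([y1, y0])
    grp = np.concatenate([np.ones(60), np.zeros(70)])
    red = np.ones((130, 1))
    res = hurdle_lrt(y, np.column_stack([red, grp]), red)
    stat, p = gaussian_two_sample_lrt(y1, y0)
    assert res["df"] == 1 and res["df_disc"] == 0
    assert res["stat"] == pytest.approx(stat, abs=1e-8)
    assert res["p"] == pytest.approx(p, abs=1e-8)
    assert res["log2fc"] == pytest.approx(y1.mean() - y0.mean(), abs=1e-8)


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(123)
    n_sims, hits, pvals = 600, 0, []
    for _ in range(n_sims):
        y = _null_y(rng)
        grp = np.zeros(200)
        grp[:100] = 1.0
        red = np.ones((200, 1))
        res = hurdle_lrt(y, np.column_stack([red, grp]), red)
        pvals.append(res["p"])
        hits += res["p"] < 0.05
    assert 0.03 <= hits / n_sims <= 0.07
    # p-values approximately uniform under the null
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_covariate_adjustment_removes_confounded_effect(rng):
    """A gene whose level tracks a covariate, with the group unbalanced
    on that covariate, is not called once the covariate is adjusted."""
    n = 400
    cov = rng.normal(size=n)
    grp = (cov + rng.normal(scale=1.0, size=n)) > 0
    y = np.maximum(1.0 + 0.8 * cov + rng.normal(scale=0.6, size=n), 0)
    red = np.column_stack([np.ones(n), cov])
    res_adj = hurdle_lrt(y, np.column_stack([red, grp]), red)
    res_raw = hurdle_lrt(y, np.column_stack([np.ones(n), grp.astype(float)]), np.ones((n, 1)))
    assert res_raw["p"] < 1e-4
    assert res_adj["p"] > 0.01


def test_moderated_lm_matches_moment_oracle(rng):
    Y = rng.normal(size=(10, 8)) * rng.uniform(0.5, 2.0, size=(10, 1))
    X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4), rng.normal(size=8)])
    scores = pd.DataFrame(Y)
    fit = moderated_lm(scores, X, contrast=1)
    t_oracle, d0_oracle, s0_oracle = ebayes_oracle(Y, X, 1)
    assert np.abs(fit["t"].to_numpy() - t_oracle).max() < 1e-8
    assert fit["d0"].iloc[0] == pytest.approx(d0_oracle, rel=1e-6)
    assert fit["s0sq"].iloc[0] == pytest.approx(s0_oracle, rel=1e-6)


def test_moderated_lm_prior_limits(rng):
    Y = rng.normal(size=(12, 9))
    X = np.column_stack([np.ones(9), np.arange(9) % 2])
    scores = pd.DataFrame(Y)
    # d0 -> inf: all posterior variances collapse to s0^2
    inf_fit = moderated_lm(scores, X, contrast=1, d0_override=np.inf)
    assert inf_fit["s2_post"].nunique() == 1
    # d0 = 0: moderated t equals ordinary t
    zero_fit = moderated_lm(scores, X, contrast=1, d0_override=0.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    dg = 9 - 2
    for i in range(12):
        beta = xtx_inv @ X.T @ Y[i]
        resid = Y[i] - X @ beta
        s2 = resid @ resid / dg
        t_ord = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
        assert zero_fit["t"].iloc[i] == pytest.approx(t_ord, rel=1e-10)


def test_equal_variances_fall_back_to_infinite_prior():
    # identical residual variance in every feature -> evar <= 0 -> d0 = inf
    base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    Y = np.vstack([base + k for k in range(6)])
    X = np.column_stack([np.ones(6), np.arange(6) % 2])
    fit = moderated_lm(pd.DataFrame(Y), X, contrast=1)
    assert np.isinf(fit["d0"].iloc[0])


def test_moderated_lm_agrees_with_limma(tmp_path, rng):
    """Cross-check the moderated t chain against the reference R
    implementation on a small matrix."""
    Y = rng.normal(size=(10, 8)) * rng.uniform(0.5, 2.0, size=(10, 1))
    X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
    fit = moderated_lm(pd.DataFrame(Y), X, contrast=1)
    np.savetxt(tmp_path / "y.txt", Y)
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        y <- as.matrix(read.table("y.txt"))
        design <- cbind(1, rep(c(0, 1), each = 4))
        fit <- eBayes(lmFit(y, design))
        cat(sprintf("%.12f\\n", fit$t[, 2]))
        cat(sprintf("prior_df %.8f\\n", fit$df.prior))
    """)
    (tmp_path / "run.R").write_text(script)
    out = subprocess.run(["Rscript", "run.R"], cwd=tmp_path, capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    lines = out.stdout.strip().splitlines()
    t_limma = np.array([float(v) for v in lines[:10]])
    d0_limma = float(lines[10].split()[1])
    assert np.abs(fit["t"].to_numpy() - t_limma).max() < 1e-6
    assert fit["d0"].iloc[0] == pytest.approx(d0_limma, rel=1e-4)


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma

    for x in (0.1, 1.0, 7.3, 150.0):
        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


def test_threshold_gates():
    """|log2FC| = 0.10 fails the 0.14 gate; FDR = 0.2 fails the 0.05 gate."""
    thr = DEThresholds()
    assert thr.logfc_min == 0.14
    table = pd.DataFrame({
        "feature": ["a", "b", "c"],
        "log2fc": [0.10, 0.50, 0.50],
        "fdr": [0.001, 0.2, 0.001],
    })
    keep = (table["log2fc"].abs() >= thr.logfc_min) & (table["fdr"] < thr.fdr_max)
    assert list(table.loc[keep, "feature"]) == ["c"]


def test_de_features_recovers_planted_genes(small_cohort):
    from snsubtype.preprocess import normalize_log

    _cfg, co = small_cohort
    t = "InN"
    e = normalize_log(co.counts[t], co.gene_ids, co.cells_of(t), co.patients)
    case = (e.cells["diagnosis"] == "case").to_numpy()
    ec = e.subset_cells(case)
    grp = (ec.cells["patient_id"].map(co.truth.subtype_of_patient) == 1).to_numpy()
    design = build_design(ec.cells, ec.patients)
    tab = de_features(ec.values, grp, design, DEThresholds(), "hurdle", kind="gene",
                      cell_type=t, subtype=1, comparison="vs_other_subtypes")
    planted_any = {g for (s, tt), f in co.truth.de_features.items() if tt == t for g, _ in f}
    planted_s1 = {g for g, _ in co.truth.de_features[(0, t)]}
    called = set(tab["feature"])
    assert len(called & planted_s1) / len(planted_s1) >= 0.6  # 240 in-group cells only
    assert len(called - planted_any) / max(len(called), 1) <= 0.15

    with pytest.raises(ValueError, match=">= 3 cells"):
        de_features(ec.values, np.arange(len(ec.cells)) < 2, design, DEThresholds(),
                    "hurdle", kind="gene", cell_type=t, subtype=1, comparison="x")


def test_de_features_sensitivity_at_two_thousand_cells():
    """Planted |log2FC| = 1 genes are recovered with sensitivity >= 0.9
    and false-discovery proportion <= 0.1 at ~2,000 cells."""
    from snsubtype.preprocess import normalize_log
    from snsubtype.synthetic import SimConfig, simulate_cohort

    cfg = SimConfig(seed=21, cell_types=["ExN"], cells_per_patient_per_type=134,
                    active_subtypes=[0], n_gene_sets=10)
    co = simulate_cohort(cfg)
    e = normalize_log(co.counts["ExN"], co.gene_ids, co.cells_of("ExN"), co.patients)
    case = (e.cells["diagnosis"] == "case").to_numpy()
    ec = e.subset_cells(case)
    assert len(ec.cells) >= 2000
    grp = (ec.cells["patient_id"].map(co.truth.subtype_of_patient) == 1).to_numpy()
    design = build_design(ec.cells, ec.patients)
    tab = de_features(ec.values, grp, design, DEThresholds(), "hurdle", kind="gene",
                      cell_type="ExN", subtype=1, comparison="vs_other_subtypes")
    planted = {g for g, _ in co.truth.de_features[(0, "ExN")]}
    called = set(tab["feature"])
    assert len(called & planted) / len(planted) >= 0.9
    assert len(called - planted) / max(len(called), 1) <= 0.1


def test_subtype_specific_intersection_and_idempotence():
    a = pd.DataFrame({"feature": ["x", "y"], "log2fc": [1.0, -1.0],
                      "comparison": "vs_other_subtypes"})
    b = pd.DataFrame({"feature": ["y", "z"], "log2fc": [-0.9, 2.0],
                      "comparison": "vs_controls"})
    out = subtype_specific(a, b)
    assert list(out["feature"]) == ["y"]
    assert out["log2fc"].iloc[0] == -1.0  # effect from the vs-subtypes table

    same = subtype_specific(a, a)
    assert list(same["feature"]) == list(a["feature"])
    empty = subtype_specific(a.iloc[:0], b)
    assert len(empty) == 0


def test_partition_unique_common_set_algebra():
    def tab(feats):
        return pd.DataFrame({"feature": feats, "log2fc": np.linspace(1, 2, len(feats))})

    unique, common, top = partition_unique_common({1: tab(["A", "B"]), 2: tab(["B", "C"]), 3: tab(["B"])})
    assert list(unique[1]["feature"]) == ["A"]
    assert list(unique[2]["feature"]) == ["C"]
    assert list(unique[3]["feature"]) == []
    assert list(common["feature"]) == ["B"]

    disjoint, common2, _ = partition_unique_common({1: tab(["A"]), 2: tab(["B"])})
    assert len(common2) == 0 and len(disjoint[1]) == 1 and len(disjoint[2]) == 1
    same, common3, _ = partition_unique_common({1: tab(["A", "B"]), 2: tab(["A", "B"])})
    assert len(common3) == 2 and all(len(t) == 0 for t in same.values())


def test_discordant_events_attribution():
    fc = pd.DataFrame({1: [0.5, 0.4, -0.3, 0.2],
                       2: [0.6, 0.5, 0.4, 0.0],
                       3: [0.7, -0.5, 0.5, -0.2]},
                      index=["all_up", "third_down", "first_down", "zero_vote"])
    events = discordant_events(list(fc.index), fc)
    by_feature = {r["feature"]: r for _, r in events.iterrows()}
    assert "all_up" not in by_feature
    assert by_feature["third_down"]["discordant_subtypes"] == [3]
    assert by_feature["first_down"]["discordant_subtypes"] == [1]
    assert by_feature["zero_vote"]["zero_excluded"]
    # 1-vs-1 sign tie after the zero is excluded: both voters listed
    assert by_feature["zero_vote"]["discordant_subtypes"] == [1, 3]

    with pytest.raises(KeyError):
        discordant_events(["missing"], fc)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
def test_bh_fdr_monotone_and_above_p(pvals):
    fdr = multipletests(pvals, method="fdr_bh")[1]
    order = np.argsort(pvals)
    assert np.all(np.diff(fdr[order]) >= -1e-12)
    assert np.all(fdr >= np.array(pvals) - 1e-12)


def test_fit_fdist_recovers_known_prior(rng):
    # variances drawn from a scaled inverse chi-square prior
    d0_true, s0_true, dg = 8.0, 1.5, 10
    g = 4000
    s2_prior = d0_true * s0_true / stats.chi2.rvs(d0_true, size=g, random_state=7)
    s2 = s2_prior * stats.chi2.rvs(dg, size=g, random_state=8) / dg
    d0, s0 = fit_fdist(s2, dg)
    assert d0 == pytest.approx(d0_true, rel=0.25)
    assert s0 == pytest.approx(s0_true, rel=0.1)
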