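"""Subtype-specific differential expression.

Genes are tested with a two-part (hurdle) model for zero-inflated
log-normalized expression: a logistic regression for whether a gene is
detected, and a Gaussian linear model for its level in the cells where
it is. The test statistic is the summed likelihood-ratio deviance of
both parts against the design without the subtype indicator, referred
to a chi-square with the summed added degrees of freedom. The reported
log2 fold change follows the hurdle convention: difference between the
groups' (detection frequency x conditional mean) products, with
covariates held at their observed values.

Gene-set scores (which are continuous and roughly Gaussian) are tested
with an ordinary linear model whose residual variances are shrunk by
empirical Bayes toward a common prior estimated by the method of
moments on the log sample variances, giving a moderated t with
augmented degrees of freedom.

Feature lists are thresholded on |log2FC| >= 0.14 (a 10% difference on
the log2 scale) and Benjamini-Hochberg FDR < 0.05; the subtype-specific
feature set is the intersection of the vs-other-subtypes and
vs-controls calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

LOGFC_COLUMNS = ["feature", "kind", "cell_type", "subtype", "comparison", "log2fc", "p", "fdr", "direction"]


@dataclass
class DEThresholds:
    logfc_min: float = 0.14
    fdr_max: float = 0.05

    def validate(self) -> "DEThresholds":
        if self.logfc_min < 0:
            raise ValueError("logfc_min must be >= 0")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")
        return self


# ---------------------------------------------------------------------------
# design helpers

def build_design(cells: pd.DataFrame, patients: pd.DataFrame,
                 covariates=("detection_rate", "age", "sex", "RIN", "PMI",
                             "region", "batch", "ribo_fraction")) -> np.ndarray:
    """Covariate design matrix (intercept first) for the given cells.

    Numeric covariates are centered and scaled; categorical ones are
    dummy-coded dropping the first level. Aliased (rank-deficient)
    columns are removed.
    """
    meta = cells.join(patients.drop(columns=[c for c in patients.columns if c in cells.columns]),
                      on="patient_id")
    cols = [np.ones(len(meta))]
    for cov in covariates:
        if cov not in meta.columns:
            continue
        col = meta[cov]
        if col.dtype.kind in "ifu":
            x = col.to_numpy(dtype=float)
            sd = x.std()
            cols.append((x - x.mean()) / sd if sd > 0 else np.zeros_like(x))
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    design = np.column_stack(cols)
    return drop_aliased(design)


def drop_aliased(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Keep a maximal linearly independent subset of columns (QR pivot)."""
    if X.shape[1] == 0:
        return X
    keep = []
    rank = 0
    # greedy left-to-right: column independent of those kept so far
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        candidate = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(candidate, tol=tol * max(1.0, np.abs(X).max())) > rank:
            keep.append(j)
            basis = candidate
            rank += 1
    return X[:, keep]


# ---------------------------------------------------------------------------
# hurdle model

def _logistic_irls(X: np.ndarray, z: np.ndarray, ridge: float = 0.0,
                   max_iter: int = 50, tol: float = 1e-10):
    """Newton/IRLS logistic fit; returns (beta, deviance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (z - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta_new = beta + step
        dev = _binom_deviance(X, z, beta_new)
        # step halving if the deviance worsens
        halvings = 0
        while dev > dev_old + 1e-8 and halvings < 10:
            step /= 2.0
            beta_new = beta + step
            dev = _binom_deviance(X, z, beta_new)
            halvings += 1
        beta = beta_new
        if abs(dev_old - dev) < tol * (abs(dev) + 1.0):
            return beta, dev, True
        dev_old = dev
    return beta, dev_old, False


def _binom_deviance(X, z, beta) -> float:
    eta = np.clip(X @ beta, -30, 30)
    loglik = np.sum(z * eta - np.log1p(np.exp(eta)))
    return float(-2.0 * loglik)


def _gaussian_deviance(X, y):
    """Gaussian ML deviance (up to constants shared by nested models):
    n * log(RSS / n). Returns (beta, deviance)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = len(y)
    rss = max(rss, 1e-12)
    return beta, n * np.log(rss / n)


def hurdle_lrt(y: np.ndarray, full_design: np.ndarray, reduced_design: np.ndarray,
               min_expressed: int | None = None) -> dict:
    """Hurdle-model likelihood-ratio test of the columns that the full
    design adds to the reduced design (appended on the right).

    Returns a dict with p, log2fc, the per-part statistics and degrees
    of freedom, and flags. A constant detection indicator drops the
    discrete part (stat 0, df 0); too few expressed cells drops the
    continuous part.
    """
    y = np.asarray(y, dtype=float)
    full = np.asarray(full_design, dtype=float)
    reduced = np.asarray(reduced_design, dtype=float)
    if full.shape[0] != len(y) or reduced.shape[0] != len(y):
        raise ValueError("designs do not share rows with y")
    k_red = reduced.shape[1]
    if full.shape[1] < k_red or not np.array_equal(full[:, :k_red], reduced):
        raise ValueError("reduced design must be the leading columns of the full design")

    flags: list[str] = []
    z = (y > 0).astype(float)
    if z.sum() == 0:
        return {"p": 1.0, "log2fc": 0.0, "stat": 0.0, "df": 0,
                "stat_disc": 0.0, "df_disc": 0, "stat_cont": 0.0, "df_cont": 0,
                "flags": ["all_zero"]}

    df_added = full.shape[1] - k_red

    # discrete part
    stat_disc, df_disc = 0.0, 0
    beta_disc = None
    if 0 < z.sum() < len(z):
        beta_full, dev_full, conv_full = _logistic_irls(full, z)
        beta_red, dev_red, conv_red = _logistic_irls(reduced, z)
        if not (conv_full and conv_red) or np.abs(beta_full).max() > 15:
            flags.append("separation_ridge")
            beta_full, dev_full, _ = _logistic_irls(full, z, ridge=1e-3)
            beta_red, dev_red, _ = _logistic_irls(reduced, z, ridge=1e-3)
        stat_disc = max(dev_red - dev_full, 0.0)
        df_disc = df_added
        beta_disc = beta_full
    else:
        flags.append("constant_detection")

    # continuous part
    expressed = y > 0
    n_pos = int(expressed.sum())
    need = (min_expressed if min_expressed is not None else full.shape[1] + 2)
    stat_cont, df_cont = 0.0, 0
    beta_cont = None
    if n_pos >= need:
        beta_cont, dev_full_c = _gaussian_deviance(full[expressed], y[expressed])
        _, dev_red_c = _gaussian_deviance(reduced[expressed], y[expressed])
        stat_cont = max(dev_red_c - dev_full_c, 0.0)
        df_cont = df_added
    else:
        flags.append("too_few_expressed")

    stat = stat_disc + stat_cont
    df = df_disc + df_cont
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    log2fc = _hurdle_log2fc(y, z, full, k_red, beta_disc, beta_cont)
    return {"p": p, "log2fc": log2fc, "stat": stat, "df": df,
            "stat_disc": stat_disc, "df_disc": df_disc,
            "stat_cont": stat_cont, "df_cont": df_cont, "flags": flags}


def _hurdle_log2fc(y, z, full, k_red, beta_disc, beta_cont) -> float:
    """Adjusted hurdle fold change: pi_g * m_g contrast with the test
    column toggled to 1/0 and covariates at observed values. Only
    defined for a single added column; falls back to the raw group
    difference when a model part is unavailable."""
    if full.shape[1] - k_red != 1:
        return float("nan")
    test = full[:, k_red]
    on = full.copy()
    off = full.copy()
    on[:, k_red] = 1.0
    off[:, k_red] = 0.0

    if beta_disc is not None:
        pi1 = float(special.expit(np.clip(on @ beta_disc, -30, 30)).mean())
        pi0 = float(special.expit(np.clip(off @ beta_disc, -30, 30)).mean())
    else:
        pi1 = pi0 = float(z.mean())
    if beta_cont is not None:
        m1 = float((on @ beta_cont).mean())
        m0 = float((off @ beta_cont).mean())
    else:
        in1 = (test > 0.5) & (y > 0)
        in0 = (test <= 0.5) & (y > 0)
        m1 = float(y[in1].mean()) if in1.any() else 0.0
        m0 = float(y[in0].mean()) if in0.any() else 0.0
    return pi1 * m1 - pi0 * m0


# ---------------------------------------------------------------------------
# moderated linear model (gene sets)

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a monotone function)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_fdist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior to sample variances:
    returns (d0, s0_squared); d0 = inf when the moment estimate of the
    log-variance spread is no larger than the sampling component."""
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(emean)
    return float(d0), float(s0sq)


def moderated_lm(scores: pd.DataFrame, design: np.ndarray, contrast: int,
                 d0_override: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-tests for every row of `scores`.

    scores : features x samples; design : samples x p (full rank);
    contrast : index of the design column whose coefficient is tested.
    Returns a DataFrame with columns coef, t, p, df, s2, s2_post.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if scores.shape[1] != n:
        raise ValueError("design rows do not match score columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    dg = n - p
    if dg < 2:
        raise ValueError("need >= 2 residual degrees of freedom")

    Y = scores.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv.T                       # features x p
    resid = Y - coef @ X.T
    s2 = (resid ** 2).sum(axis=1) / dg
    se_unscaled = np.sqrt(xtx_inv[contrast, contrast])

    d0, s0sq = fit_fdist(s2, dg)
    if d0_override is not None:
        d0 = d0_override
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg) if d0 > 0 else s2
        df_total = d0 + dg
    tstat = coef[:, contrast] / (np.sqrt(s2_post) * se_unscaled)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return pd.DataFrame(
        {"coef": coef[:, contrast], "t": tstat, "p": pvals,
         "df": df_total, "s2": s2, "s2_post": s2_post, "d0": d0, "s0sq": s0sq},
        index=scores.index,
    )


# ---------------------------------------------------------------------------
# feature tables

def de_features(values: pd.DataFrame, group_mask: np.ndarray, covariate_design: np.ndarray,
                thresholds: DEThresholds, method: str, *, kind: str,
                cell_type: str, subtype: int, comparison: str,
                keep_all: bool = False) -> pd.DataFrame:
    """Test every feature (row of `values`) for the group effect and
    return the thresholded DETable rows for one comparison.

    group_mask marks the subtype's cells among the columns of `values`;
    covariate_design is the reduced design (intercept + covariates).
    method "hurdle" fits the two-part model per gene; "moderated" fits
    the empirical-Bayes linear model across all features at once.
    With keep_all=True the unthresholded table is returned (column
    `significant` marks the thresholded calls).
    """
    thresholds.validate()
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.sum() < 3 or (~group_mask).sum() < 3:
        raise ValueError("each group needs >= 3 cells")
    reduced = np.asarray(covariate_design, dtype=float)
    full = np.column_stack([reduced, group_mask.astype(float)])
    if np.linalg.matrix_rank(full) <= np.linalg.matrix_rank(reduced):
        raise ValueError("group indicator is aliased with the covariates")

    if method == "hurdle":
        rows = []
        for feature in values.index:
            res = hurdle_lrt(values.loc[feature].to_numpy(), full, reduced)
            rows.append((feature, res["log2fc"], res["p"]))
        table = pd.DataFrame(rows, columns=["feature", "log2fc", "p"])
    elif method == "moderated":
        fit = moderated_lm(values, full, contrast=full.shape[1] - 1)
        table = pd.DataFrame({"feature": values.index, "log2fc": fit["coef"].to_numpy(),
                              "p": fit["p"].to_numpy()})
    else:
        raise ValueError(f"unknown method {method!r}")

    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    table["kind"] = kind
    table["cell_type"] = cell_type
    table["subtype"] = subtype
    table["comparison"] = comparison
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table["significant"] = (table["log2fc"].abs() >= thresholds.logfc_min) & (table["fdr"] < thresholds.fdr_max)
    table = table[LOGFC_COLUMNS + ["significant"]]
    if keep_all:
        return table.reset_index(drop=True)
    return table[table["significant"]].drop(columns="significant").reset_index(drop=True)


def subtype_specific(de_vs_subtypes: pd.DataFrame, de_vs_controls: pd.DataFrame) -> pd.DataFrame:
    """Intersection rule: features significant both against the other
    subtypes and against controls; effect size and direction are taken
    from the vs-other-subtypes comparison."""
    common = set(de_vs_subtypes["feature"]) & set(de_vs_controls["feature"])
    out = de_vs_subtypes[de_vs_subtypes["feature"].isin(common)].copy()
    out["comparison"] = "subtype_specific"
    return out.reset_index(drop=True)


def partition_unique_common(tables: dict[int, pd.DataFrame], top_n: int = 10,
                            ) -> tuple[dict[int, pd.DataFrame], pd.DataFrame, dict[int, pd.DataFrame]]:
    """Partition per-subtype feature tables into features unique to one
    subtype and features shared by all subtypes (within a cell type).

    Returns (unique tables per subtype, common-feature frame, top-N
    unique features per subtype ranked by |log2fc|).
    """
    membership: dict[str, set[int]] = {}
    for s, tab in tables.items():
        for f in tab["feature"]:
            membership.setdefault(f, set()).add(s)
    unique = {}
    top = {}
    for s, tab in tables.items():
        mask = tab["feature"].map(lambda f: membership[f] == {s}).astype(bool)
        unique[s] = tab.loc[mask].reset_index(drop=True)
        top[s] = unique[s].reindex(
            unique[s]["log2fc"].abs().sort_values(ascending=False).index
        ).head(top_n).reset_index(drop=True)
    all_subtypes = set(tables)
    common_feats = sorted(f for f, ms in membership.items() if ms == all_subtypes)
    common = pd.DataFrame({"feature": common_feats})
    return unique, common, top


def discordant_events(common_features, log2fc_vs_controls: pd.DataFrame) -> pd.DataFrame:
    """Features shared by all subtypes whose vs-control effect signs
    disagree; each event is attributed to the minority-sign subtype(s).

    log2fc_vs_controls : features x subtypes frame of vs-control log2FC.
    Zero fold changes carry no sign and are excluded from the vote (the
    event row flags them).
    """
    rows = []
    for f in common_features:
        if f not in log2fc_vs_controls.index:
            raise KeyError(f"no vs-control log2fc for common feature {f!r}")
        fc = log2fc_vs_controls.loc[f]
        signs = {s: np.sign(v) for s, v in fc.items() if np.sign(v) != 0}
        zero_flag = len(signs) < len(fc)
        values = list(signs.values())
        if len(set(values)) <= 1:
            continue
        n_pos = sum(1 for v in values if v > 0)
        n_neg = len(values) - n_pos
        minority = 1 if n_pos < n_neg else (-1 if n_neg < n_pos else 0)
        if minority == 0:
            attributed = sorted(signs)          # exact tie: all voters listed
        else:
            attributed = sorted(s for s, v in signs.items() if v == minority)
        rows.append({"feature": f, "discordant_subtypes": attributed,
                     "signs": {s: int(v) for s, v in signs.items()},
                     "zero_excluded": zero_flag})
    return pd.DataFrame(rows, columns=["feature", "discordant_subtypes", "signs", "zero_excluded"])
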