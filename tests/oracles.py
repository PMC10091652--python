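"""Independent brute-force reference implementations used only by tests.

Each oracle is coded directly from the defining formulas with plain
loops and none of the package's numerical shortcuts, so agreement with
the package is a genuine dual-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import digamma, polygamma
from scipy.stats import norm, chi2


# ---------------------------------------------------------------- GSVA

def gsva_oracle(values: np.ndarray, gene_names: list[str], sets: dict[str, list[str]],
                tau: float = 1.0, mx_diff: bool = True, min_size: int = 1) -> dict[str, list[float]]:
    """Naive kcdf -> rank -> walk scoring, one (set, sample) at a time."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    # Gaussian kernel CDF, bandwidth sd/4
    z = np.zeros_like(values)
    for i in range(p):
        s = np.std(values[i], ddof=1)
        h = s / 4.0
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += norm.cdf((values[i, j] - values[i, k]) / h)
            z[i, j] = acc / n

    universe = set(gene_names)
    out = {}
    for name, members in sets.items():
        kept = [g for g in members if g in universe]
        if len(kept) < min_size:
            continue
        member_set = set(kept)
        scores = []
        for j in range(n):
            # rank genes by decreasing z, ties by input order (stable)
            order = sorted(range(p), key=lambda i: (-z[i, j], i))
            r = {}
            for rank_pos, gi in enumerate(order, start=1):
                r[gi] = abs(p / 2.0 - rank_pos)
            total = sum(r[gi] ** tau for gi in range(p) if gene_names[gi] in member_set)
            size = len(member_set)
            nu = []
            in_count = 0.0
            out_count = 0
            for gi in order:
                if gene_names[gi] in member_set:
                    in_count += (r[gi] ** tau) / total if total > 0 else 1.0 / size
                else:
                    out_count += 1
                nu.append(in_count - out_count / (p - size))
            nu = np.array(nu)
            if mx_diff:
                score = max(nu.max(), 0.0) + min(nu.min(), 0.0)
            else:
                score = nu[int(np.argmax(np.abs(nu)))]
            scores.append(score)
        out[name] = scores
    return out


# ----------------------------------------------------------------- SNF

def snf_oracle(views: list[np.ndarray], K: int, T: int) -> np.ndarray:
    """Step-by-step cross-diffusion following the written update rules."""

    def normalize(w):
        n = w.shape[0]
        p = np.zeros_like(w)
        for i in range(n):
            offsum = sum(w[i, j] for j in range(n) if j != i)
            for j in range(n):
                p[i, j] = 0.5 if i == j else w[i, j] / (2.0 * offsum)
        return p

    def knn_kernel(w, K):
        n = w.shape[0]
        s = np.zeros_like(w)
        for i in range(n):
            order = sorted((j for j in range(n) if j != i), key=lambda j: (-w[i, j], j))
            nbrs = order[:K]
            tot = sum(w[i, j] for j in nbrs)
            for j in nbrs:
                s[i, j] = w[i, j] / tot
        return s

    m = len(views)
    P = [normalize(np.asarray(v, float)) for v in views]
    S = [knn_kernel(np.asarray(v, float), K) for v in views]
    for _ in range(T):
        new = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            q = S[v] @ others @ S[v].T
            q = (q + q.T) / 2.0
            new.append(normalize(q))
        P = new
    fused = sum(P) / m
    fused = (fused + fused.T) / 2.0
    return normalize(fused)


# ----------------------------------------------------- moderated t (eBayes)

def ebayes_oracle(Y: np.ndarray, X: np.ndarray, contrast: int):
    """Moment-equation moderated t, with the trigamma inverse found by
    bisection rather than Newton."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    dg = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = (xtx_inv @ X.T @ Y.T).T
    resid = Y - beta @ X.T
    s2 = (resid ** 2).sum(axis=1) / dg

    e = np.log(s2) - digamma(dg / 2.0) + math.log(dg / 2.0)
    ebar = e.mean()
    G = len(e)
    evar = ((e - ebar) ** 2).sum() / (G - 1) - polygamma(1, dg / 2.0)
    if evar > 0:
        # bisection for trigamma(x) = evar
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2.0 * math.sqrt(lo * hi)
        s0sq = math.exp(ebar + digamma(d0 / 2.0) - math.log(d0 / 2.0))
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
    else:
        d0 = math.inf
        s0sq = math.exp(ebar)
        s2_post = np.full_like(s2, s0sq)
    se = math.sqrt(xtx_inv[contrast, contrast])
    t = beta[:, contrast] / (np.sqrt(s2_post) * se)
    return t, d0, s0sq


# --------------------------------------------------- classical Gaussian LRT

def gaussian_two_sample_lrt(y1: np.ndarray, y0: np.ndarray):
    """Closed-form LRT of equal means (common unknown variance, ML):
    stat = n log(RSS0 / RSS1), chi-square df 1."""
    y = np.concatenate([y1, y0])
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1 = float(((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum())
    stat = n * math.log(rss0 / rss1)
    return stat, float(chi2.sf(stat, 1))


# -------------------------------------------------------- hypergeometric

def hypergeom_enrichment_oracle(query: set, reference: set, universe: list):
    """P(overlap >= observed) by enumeration of every |query|-subset."""
    observed = len(query & reference)
    N = len(query)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, N):
        total += 1
        if len(set(draw) & reference) >= observed:
            hits += 1
    return observed, hits / total
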