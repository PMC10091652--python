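"""Similarity network fusion, spectral clustering, and model selection.

Given one affinity matrix per data view (e.g., one per cell type, or
gene-level vs gene-set-level), cross-diffusion iteratively updates each
view's row-stochastic similarity through the average of the others,
restricted through each view's K-nearest-neighbor kernel, then averages
the diffused matrices into a single fused network. Patients are
clustered on the fused network by normalized spectral clustering, with
the number of clusters chosen by the Laplacian eigen-gap and a
rotation-cost criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .containers import AffinityMatrix, PatientProfileMatrix, SubtypeAssignment


@dataclass
class SNFParams:
    """K: neighborhood size for the local kernel and the kernel scale
    heuristic; T: diffusion iterations; mu: kernel bandwidth multiplier;
    k_range: candidate cluster numbers; seed: k-means restarts."""

    K: int = 3
    T: int = 100
    mu: float = 0.5
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    seed: int = 0
    kernel: str = "exponential"   # or "density"
    standardize: bool = True

    def validate(self, n_patients: int | None = None) -> "SNFParams":
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if n_patients is not None and self.K >= n_patients:
            raise ValueError(f"K={self.K} must be < n_patients={n_patients}")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.kernel not in ("exponential", "density"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        return self


def squared_euclidean_distances(profiles: PatientProfileMatrix | pd.DataFrame,
                                standardize: bool = True) -> pd.DataFrame:
    """Pairwise squared Euclidean distances between patient profiles.

    With standardize=True each feature is centered and scaled to unit
    variance first; constant features are dropped.
    """
    frame = profiles.values if isinstance(profiles, PatientProfileMatrix) else profiles
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    x = frame.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    sq = (x ** 2).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=frame.index, columns=frame.index)


def affinity_matrix(dist: pd.DataFrame | np.ndarray, K: int = 3, mu: float = 0.5,
                    kernel: str = "exponential") -> AffinityMatrix:
    """Locally scaled kernel affinity from a squared-distance matrix.

    eps_ij = (m_i + m_j + d_ij) / 3 with m_i the mean of the K smallest
    off-diagonal distances in row i. The default kernel is
    W_ij = exp(-d_ij / (mu * eps_ij)); the "density" variant is the
    Gaussian-density form exp(-d_ij / (2 (mu eps_ij)^2)) normalized by
    sqrt(2 pi) mu eps_ij.
    """
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else [str(i) for i in range(len(dist))]
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < n={n}")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    off = d + np.diag(np.full(n, np.inf))
    m = np.sort(off, axis=1)[:, :K].mean(axis=1)
    eps = (m[:, None] + m[None, :] + d) / 3.0
    if kernel == "exponential":
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(d == 0.0, 1.0, np.exp(-d / (mu * eps)))
    elif kernel == "density":
        sigma = mu * eps
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(
                d == 0.0, 1.0,
                np.exp(-d / (2.0 * sigma ** 2)) / (np.sqrt(2.0 * np.pi) * sigma),
            )
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return AffinityMatrix(w, ids, normalized=False)


def full_normalize(W: AffinityMatrix | np.ndarray) -> AffinityMatrix:
    """Row-stochastic normalization: P_ij = W_ij / (2 sum_{k!=i} W_ik)
    off-diagonal, P_ii = 1/2; every row sums to 1."""
    ids, w = _unpack(W)
    n = w.shape[0]
    offsum = w.sum(axis=1) - np.diag(w)
    dead = np.flatnonzero(offsum <= 0)
    if dead.size:
        raise ValueError(f"rows with all-zero off-diagonal affinity: {[ids[i] for i in dead]}")
    p = w / (2.0 * offsum[:, None])
    np.fill_diagonal(p, 0.5)
    return AffinityMatrix(p, ids, normalized=True)


def local_kernel(W: AffinityMatrix | np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic K-nearest-neighbor kernel S: each row keeps its K
    strongest off-diagonal affinities (ties by ascending index),
    renormalized to sum 1."""
    ids, w = _unpack(W)
    n = w.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < n={n}")
    s = np.zeros_like(w)
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        # stable sort on descending affinity -> ties broken by ascending index
        nbrs = np.argsort(-row, kind="stable")[:K]
        total = w[i, nbrs].sum()
        if total <= 0:
            raise ValueError(f"all {K} neighbors of {ids[i]} have zero affinity")
        s[i, nbrs] = w[i, nbrs] / total
    return s


def snf_fuse(views: list[AffinityMatrix], params: SNFParams,
             check_conservation: bool = False) -> AffinityMatrix:
    """Cross-diffusion fusion of raw affinity views into one network.

    For m >= 2 views: P_v = full_normalize(W_v), S_v = local_kernel(W_v, K);
    T iterations of P_v <- S_v (mean of other P_u) S_v^T followed by
    symmetrization and re-normalization; the fused network is the
    normalized symmetrized mean of the final P_v. A single view is
    simply normalized.

    check_conservation asserts after every iteration that rows still
    sum to 1 (within 1e-8) and that the row-scaling asymmetry has not
    been amplified beyond the level already present in the normalized
    input views (row-stochastic scaling of a symmetric kernel is only
    approximately symmetric).
    """
    if not views:
        raise ValueError("need at least one view")
    ids = views[0].patient_ids
    for v in views[1:]:
        if v.patient_ids != ids:
            raise ValueError("patient order mismatch across views")
    params.validate(n_patients=len(ids))
    if len(views) == 1:
        return full_normalize(views[0])

    m = len(views)
    P = [full_normalize(v).values for v in views]
    S = [local_kernel(v, params.K) for v in views]
    base_asym = max(np.abs(p - p.T).max() for p in P)
    for _ in range(params.T):
        new = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            q = S[v] @ others @ S[v].T
            q = (q + q.T) / 2.0
            new.append(full_normalize(AffinityMatrix(q, ids, normalized=False)).values)
        P = new
        if check_conservation:
            for q in P:
                assert np.allclose(q.sum(axis=1), 1.0, atol=1e-8), "fusion lost row sums"
                asym = np.abs(q - q.T).max()
                assert asym <= max(1e-8, 2.0 * base_asym), "fusion amplified asymmetry"
    fused = sum(P) / m
    fused = (fused + fused.T) / 2.0
    return full_normalize(AffinityMatrix(fused, ids, normalized=False))


def _laplacian_eigen(P: AffinityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the symmetric normalized Laplacian
    L = I - D^{-1/2} P D^{-1/2}, eigenvalues ascending."""
    w = P.values
    deg = w.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    lap = np.eye(len(deg)) - dinv[:, None] * w * dinv[None, :]
    lap = (lap + lap.T) / 2.0
    evals, evecs = np.linalg.eigh(lap)
    return evals, evecs


def spectral_cluster(P: AffinityMatrix, k: int, seed: int = 0, n_init: int = 20) -> SubtypeAssignment:
    """Normalized spectral clustering (leading Laplacian eigenvectors,
    row-normalized, seeded k-means). Labels are 1..k, renumbered by
    descending cluster size then first-patient index."""
    n = P.n
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    labels01 = np.zeros(n, dtype=int)
    if k > 1:
        _, evecs = _laplacian_eigen(P)
        z = evecs[:, :k]
        norms = np.linalg.norm(z, axis=1)
        norms[norms == 0] = 1.0
        z = z / norms[:, None]
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels01 = km.fit_predict(z)
    labels = _relabel(labels01) + 1
    series = pd.Series(labels, index=pd.Index(P.patient_ids, name="patient_id"), name="subtype")
    return SubtypeAssignment(series, k=k).validate()


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels by descending cluster size; ties by the index of
    the cluster's first member."""
    uniq = np.unique(labels)
    order = sorted(uniq, key=lambda c: (-int((labels == c).sum()), int(np.argmax(labels == c))))
    mapping = {c: i for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels])


def _varimax(z: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation: orthogonally rotate the column basis so each
    row loads on as few columns as possible (indicator-like structure)."""
    n, k = z.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        zr = z @ rot
        u, s, vt = np.linalg.svd(z.T @ (zr ** 3 - zr * (zr ** 2).sum(axis=0) / n))
        rot = u @ vt
        var = s.sum()
        if var_old != 0 and (var - var_old) < tol * var:
            break
        var_old = var
    return z @ rot


def estimate_n_clusters(P: AffinityMatrix, k_range=(2, 3, 4, 5)) -> tuple[int, int, dict]:
    """Choose the number of clusters by (a) the largest Laplacian
    eigen-gap lambda_{k+1} - lambda_k and (b) the smallest alignment
    cost of the leading eigenvectors.

    The alignment cost J(k) = sum_i 1 / max_j Z_ij^2 is evaluated on
    varimax-rotated, row-normalized leading eigenvectors: the rotation
    resolves the arbitrary basis within the leading eigenspace, so J
    attains its floor (one dominant coordinate per row) exactly when
    the eigenspace carries indicator structure for k clusters.
    """
    k_range = sorted(k_range)
    if max(k_range) >= P.n:
        raise ValueError("max(k_range) must be < number of patients")
    evals, evecs = _laplacian_eigen(P)
    eigengaps = {k: float(evals[k] - evals[k - 1]) for k in k_range}
    rotation = {}
    for k in k_range:
        z = _varimax(evecs[:, :k]) if k > 1 else evecs[:, :1]
        norms = np.linalg.norm(z, axis=1)
        norms[norms == 0] = 1.0
        z2 = (z / norms[:, None]) ** 2
        # rows are unit vectors, so per-row cost is 1 / max_j Z_ij^2;
        # an all-zero eigenvector row contributes the worst cost k
        top = np.maximum(z2.max(axis=1), 1.0 / k)
        rotation[k] = float((1.0 / top).sum()) / P.n
    best_eigengap = max(k_range, key=lambda k: (eigengaps[k], -k))
    best_rotation = min(k_range, key=lambda k: (rotation[k], k))
    diagnostics = {
        "eigenvalues": evals.tolist(),
        "eigengap_by_k": eigengaps,
        "rotation_cost_by_k": rotation,
    }
    return best_eigengap, best_rotation, diagnostics


def silhouette_from_affinity(P: AffinityMatrix, labels: pd.Series | np.ndarray) -> float:
    """Mean silhouette of a partition under the affinity-derived
    distance d_ij = 1 - P_ij / max_{i != j} P_ij (diagonal 0).

    Singleton clusters contribute 0 (sklearn's convention); a single
    cluster overall is an error.
    """
    lab = np.asarray(labels.loc[P.patient_ids] if isinstance(labels, pd.Series) else labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    w = P.values.copy()
    np.fill_diagonal(w, 0.0)
    top = w.max()
    if top <= 0:
        raise ValueError("affinity matrix has no positive off-diagonal entries")
    d = 1.0 - w / top
    np.fill_diagonal(d, 0.0)
    return float(silhouette_samples(d, lab, metric="precomputed").mean())


def _unpack(W) -> tuple[list[str], np.ndarray]:
    if isinstance(W, AffinityMatrix):
        return list(W.patient_ids), W.values.copy()
    w = np.asarray(W, dtype=float)
    return [str(i) for i in range(w.shape[0])], w.copy()
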