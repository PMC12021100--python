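"""Similarity network fusion (SNF) patient stratification.

Per-layer sample affinities are built with a locally scaled Gaussian kernel
on z-scored features, fused by cross-diffusion, and clustered spectrally.
The number of clusters is chosen by the maximal eigengap of the normalized
graph Laplacian and, as a second criterion, the minimal eigenvector-rotation
(alignment) cost of self-tuning spectral clustering.  Concordance between the
fused and per-layer networks is quantified by normalized mutual information.

A simplified split-based similarity classifier validates the clustering the
way patient-similarity-network classifiers do: each test sample is assigned
to the cluster whose training members it most resembles, averaged over data
views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, svd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .config import SNFConfig
from .layers import OmicsLayer, SampleTable

SNFParams = SNFConfig  # field-facing alias: the SNF parameter block


@dataclass
class AffinityMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    provenance: str = "layer"

    def __post_init__(self) -> None:
        W = np.asarray(self.matrix, dtype=float)
        if W.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("affinity matrix shape mismatch")
        if np.max(np.abs(W - W.T)) > 1e-10:
            raise ValueError("affinity matrix not symmetric")
        if (W < -1e-12).any():
            raise ValueError("affinity matrix has negative entries")
        self.matrix = W


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: np.ndarray
    n_clusters: int
    eigengap: dict[int, float] = field(default_factory=dict)
    rotation_cost: dict[int, float] = field(default_factory=dict)
    layer_nmi: dict[str, float] = field(default_factory=dict)


def variance_filter(layer: OmicsLayer, threshold: float = 0.2) -> OmicsLayer:
    """Drop features with variance strictly below ``threshold``."""
    var = np.var(layer.values, axis=0)
    keep = var >= threshold
    if not keep.any():
        raise ValueError("variance filter removed every feature")
    dropped = int((~keep).sum())
    out = OmicsLayer(layer.layer_kind, list(layer.sample_ids),
                     [f for f, k in zip(layer.feature_ids, keep) if k],
                     layer.values[:, keep].copy())
    out.n_imputed = layer.n_imputed
    if dropped:
        warnings.warn(f"variance filter removed {dropped} features "
                      f"({layer.layer_kind.value})", stacklevel=2)
    return out


def _zscore(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance feature cannot be z-scored; apply variance_filter")
    return (values - mu) / sd


def squared_distances(values: np.ndarray) -> np.ndarray:
    sq = np.sum(values ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * values @ values.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def build_affinity(layer: OmicsLayer, params: SNFParams) -> AffinityMatrix:
    """Locally scaled Gaussian kernel affinity.

    W(i,j) = exp(-d2(i,j) / (alpha * eps(i,j))) with
    eps(i,j) = (mean d2 over i's K nearest neighbours
                + mean over j's + d2(i,j)) / 3, so W(i,i) = 1.
    """
    n = layer.n_samples
    if n < params.K + 1:
        raise ValueError(f"need at least K+1={params.K + 1} samples, have {n}")
    d2 = squared_distances(_zscore(layer.values))
    # mean squared distance to the K nearest neighbours, self excluded
    sorted_d2 = np.sort(d2, axis=1)[:, 1:params.K + 1]
    mu = sorted_d2.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + d2) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-d2 / (params.alpha * eps))
    W[~np.isfinite(W)] = 1.0  # d2 = 0 and eps = 0: identical samples
    W = (W + W.T) / 2.0
    return AffinityMatrix(list(layer.sample_ids), W, layer.layer_kind.value)


def _normalize_p(W: np.ndarray) -> np.ndarray:
    """Full-kernel normalization: off-diagonal row mass 1/2, diagonal 1/2."""
    P = W.copy()
    np.fill_diagonal(P, 0.0)
    rowsum = P.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    P = P / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _sinkhorn_symmetric(W: np.ndarray, tol: float = 1e-13, max_iter: int = 10000) -> np.ndarray:
    """Symmetric diagonal scaling to the doubly stochastic limit, so the
    final fused matrix is simultaneously symmetric, nonnegative and
    row-stochastic (cluster structure is preserved under diagonal scaling)."""
    A = W.copy()
    for _ in range(max_iter):
        r = A.sum(axis=1)
        if np.max(np.abs(r - 1.0)) < tol:
            break
        d = 1.0 / np.sqrt(r)
        A = A * d[:, None] * d[None, :]
    return (A + A.T) / 2.0


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Sparse row-stochastic kernel keeping each row's K nearest neighbours."""
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        w = W[i].copy()
        w[i] = -np.inf
        # ties broken by sample order (stable argsort on negated values)
        nn = np.argsort(-w, kind="stable")[:K]
        S[i, nn] = W[i, nn]
    rowsum = S.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    return S / rowsum[:, None]


def snf_fuse(affinities: list[AffinityMatrix], params: SNFParams) -> AffinityMatrix:
    """Cross-diffusion fusion of two or more per-layer affinity matrices."""
    if len(affinities) < 2:
        raise ValueError("need at least two layers to fuse")
    ids = affinities[0].sample_ids
    for a in affinities[1:]:
        if a.sample_ids != ids:
            raise ValueError("sample mismatch across layers")
    P = [_normalize_p(a.matrix) for a in affinities]
    S = [_knn_kernel(a.matrix, params.K) for a in affinities]
    m = len(P)
    for _ in range(params.T):
        new = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            Pv = (Pv + Pv.T) / 2.0
            new.append(_normalize_p(Pv))
        P = new
    fused = sum(P) / m
    fused = _sinkhorn_symmetric((fused + fused.T) / 2.0)
    return AffinityMatrix(list(ids), fused, "fused")


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    A = W.copy()
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    deg[deg == 0] = np.finfo(float).eps
    dinv = 1.0 / np.sqrt(deg)
    L = -A * dinv[:, None] * dinv[None, :]
    np.fill_diagonal(L, 1.0)
    return (L + L.T) / 2.0


def spectral_cluster(W: AffinityMatrix, C: int, seed: int = 0) -> np.ndarray:
    """Normalized-Laplacian spectral clustering; labels in 1..C."""
    if C < 2:
        raise ValueError("C must be >= 2")
    n = len(W.sample_ids)
    if C >= n:
        return np.arange(1, n + 1)
    A = W.matrix.copy()
    np.fill_diagonal(A, 0.0)
    n_comp, comp = connected_components((A > 0).astype(int), directed=False)
    if n_comp > C:
        warnings.warn(f"graph has {n_comp} components > C={C}; labelling by component",
                      stacklevel=2)
        return comp + 1
    L = _normalized_laplacian(W.matrix)
    vals, vecs = eigh(L, subset_by_index=(0, C - 1))
    U = vecs
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=C, n_init=20, random_state=seed)
    return km.fit_predict(U) + 1


def _discretise_onehot(Z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(Z)
    out[np.arange(Z.shape[0]), np.argmax(Z, axis=1)] = 1.0
    return out


def _rotation_cost(U: np.ndarray, max_iter: int = 30) -> float:
    """Self-tuning spectral-clustering alignment cost of eigenvectors ``U``.

    The eigenvector block is rotated toward a partition-indicator structure
    with the SVD-based discretisation of Yu & Shi; the reported cost is
    sum_i sum_j Z_ij^2 / max_j Z_ij^2 of the rotated block, which attains its
    minimum n when every row is one-hot (perfectly aligned clusters).
    """
    n, k = U.shape
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    V = U / norms
    # initial rotation: greedily pick mutually dissimilar rows
    R = np.zeros((k, k))
    R[:, 0] = V[n // 2]
    c = np.zeros(n)
    for j in range(1, k):
        c += np.abs(V @ R[:, j - 1])
        R[:, j] = V[int(np.argmin(c))]
    last = 0.0
    for _ in range(max_iter):
        disc = _discretise_onehot(V @ R)
        u, s, vt = svd(disc.T @ V)
        ncut = 2.0 * (n - s.sum())
        if abs(ncut - last) < 1e-12:
            break
        last = ncut
        R = (u @ vt).T
    Z = V @ R
    Z2 = Z ** 2
    m = Z2.max(axis=1)
    m[m == 0] = np.finfo(float).eps
    return float(np.sum(Z2 / m[:, None]))


def estimate_num_clusters(W: AffinityMatrix, candidates=None) -> dict:
    """Eigengap and rotation-cost model selection over a candidate range."""
    n = len(W.sample_ids)
    if candidates is None:
        candidates = range(2, min(10, n - 1) + 1)
    candidates = [int(c) for c in candidates]
    if min(candidates) < 2 or max(candidates) > n - 1:
        raise ValueError("candidate range must lie within [2, n-1]")
    L = _normalized_laplacian(W.matrix)
    vals, vecs = eigh(L)
    eigengap = {c: float(vals[c] - vals[c - 1]) for c in candidates}
    rotation = {c: _rotation_cost(vecs[:, :c]) for c in candidates}
    best_gap = max(candidates, key=lambda c: (eigengap[c], -c))
    best_rot = min(candidates, key=lambda c: (rotation[c], c))
    return {"best_by_eigengap": best_gap, "best_by_rotation_cost": best_rot,
            "eigengap": eigengap, "rotation_cost": rotation,
            "eigenvalues": vals[: max(candidates) + 1].tolist()}


def nmi_concordance(fused: AffinityMatrix, single_layers: list[AffinityMatrix],
                    C: int, seed: int = 0) -> dict[str, float]:
    """NMI between fused-network clusters and each single-layer clustering."""
    for a in single_layers:
        if a.sample_ids != fused.sample_ids:
            raise ValueError("sample mismatch between fused and layer affinity")
    ref = spectral_cluster(fused, C, seed)
    out = {}
    for a in single_layers:
        lab = spectral_cluster(a, C, seed)
        out[a.provenance] = float(normalized_mutual_info_score(
            ref, lab, average_method="arithmetic"))
    return out


def stratify(layers: list[OmicsLayer], params: SNFParams | None = None,
             seed: int = 0) -> ClusterAssignment:
    """Full stratification: filter, per-layer affinity, fusion, model
    selection at the eigengap optimum, and per-layer NMI concordance."""
    params = params or SNFParams()
    filtered = [variance_filter(l, params.variance_threshold) for l in layers]
    affinities = [build_affinity(l, params) for l in filtered]
    fused = snf_fuse(affinities, params)
    lo, hi = params.cluster_range
    hi = min(hi, fused.matrix.shape[0] - 1)
    diag = estimate_num_clusters(fused, range(lo, hi + 1))
    C = params.n_clusters or diag["best_by_eigengap"]
    labels = spectral_cluster(fused, C, seed)
    nmi = nmi_concordance(fused, affinities, C, seed)
    out = ClusterAssignment(list(fused.sample_ids), labels, C,
                            diag["eigengap"], diag["rotation_cost"], nmi)
    out.fused = fused
    return out


@dataclass
class ValidationReport:
    auroc: float
    aupr: float
    roc_points: np.ndarray
    pr_points: np.ndarray
    mean_confusion: np.ndarray
    mean_accuracy: float
    per_split_accuracy: list[float]


def _similarity_scores(train_X: np.ndarray, test_X: np.ndarray,
                       train_lab: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Mean Pearson similarity of each test sample to each cluster's members."""
    tr = train_X - train_X.mean(axis=1, keepdims=True)
    te = test_X - test_X.mean(axis=1, keepdims=True)
    tr_n = np.linalg.norm(tr, axis=1, keepdims=True)
    te_n = np.linalg.norm(te, axis=1, keepdims=True)
    tr_n[tr_n == 0] = 1.0
    te_n[te_n == 0] = 1.0
    sim = (te / te_n) @ (tr / tr_n).T
    return np.stack([sim[:, train_lab == c].mean(axis=1) for c in clusters], axis=1)


def _clinical_scores(train_x: np.ndarray, test_x: np.ndarray,
                     train_lab: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    rng_ = np.ptp(train_x)
    if rng_ == 0:
        return np.zeros((len(test_x), len(clusters)))
    diff = np.abs(test_x[:, None] - train_x[None, :]) / rng_
    return np.stack([-diff[:, train_lab == c].mean(axis=1) for c in clusters], axis=1)


def validate_clusters(layers: list[OmicsLayer], samples: SampleTable,
                      labels, train_frac: float = 0.8, n_splits: int = 20,
                      seed: int = 0) -> ValidationReport:
    """Split-based similarity-classifier validation of a cluster assignment.

    Per split, each held-out sample is scored against every cluster by mean
    Pearson similarity (omics views) and negative normalized absolute
    difference (continuous clinical views), averaged across views; argmax is
    the prediction.  ROC/PR use the score margin of the second cluster.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2 or min((labels == c).sum() for c in clusters) < 5:
        raise ValueError("need >= 2 clusters with >= 5 members each")
    rng = np.random.default_rng(seed)
    n = len(labels)
    omics = [_zscore(l.values) for l in layers]
    clinical = []
    if samples.covariates is not None:
        for col in samples.covariates.columns:
            if np.issubdtype(samples.covariates[col].dtype, np.number):
                clinical.append(samples.covariates[col].to_numpy(dtype=float))
    confusions, accs = [], []
    margins, truths = [], []
    for _ in range(n_splits):
        for _attempt in range(100):
            train = rng.random(n) < train_frac
            if all(((labels == c) & train).any() for c in clusters) and (~train).any():
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not draw a split containing every cluster")
        test = ~train
        scores = np.zeros((test.sum(), len(clusters)))
        n_views = 0
        for X in omics:
            scores += _similarity_scores(X[train], X[test], labels[train], clusters)
            n_views += 1
        for x in clinical:
            scores += _clinical_scores(x[train], x[test], labels[train], clusters)
            n_views += 1
        scores /= n_views
        pred = clusters[np.argmax(scores, axis=1)]
        true = labels[test]
        conf = np.array([[np.sum((true == a) & (pred == b)) for b in clusters]
                         for a in clusters], dtype=float)
        confusions.append(conf)
        accs.append(float(np.trace(conf) / conf.sum()))
        if len(clusters) == 2:
            margins.extend((scores[:, 1] - scores[:, 0]).tolist())
            truths.extend((true == clusters[1]).astype(int).tolist())
    auroc = aupr = float("nan")
    roc_pts = pr_pts = np.empty((0, 2))
    if margins:
        from sklearn.metrics import average_precision_score, precision_recall_curve, \
            roc_auc_score, roc_curve
        auroc = float(roc_auc_score(truths, margins))
        aupr = float(average_precision_score(truths, margins))
        fpr, tpr, _ = roc_curve(truths, margins)
        prec, rec, _ = precision_recall_curve(truths, margins)
        roc_pts = np.column_stack([fpr, tpr])
        pr_pts = np.column_stack([rec, prec])
    return ValidationReport(auroc, aupr, roc_pts, pr_pts,
                            np.mean(confusions, axis=0), float(np.mean(accs)),
                            accs)
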