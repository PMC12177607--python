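"""Chemical-space processing: descriptor cleaning, correlation filtering, PCA,
K-means with information-criterion cluster-number selection, and
centroid-proximity representative selection.

The clustering pipeline mirrors the standard odorant-selection workflow:
molecular descriptors are cleaned, near-collinear columns (|Pearson r| above
a threshold, default 0.95) are dropped, the matrix is z-scored and reduced by
PCA, K-means partitions the reduced space, and the cluster number is chosen
by consensus of AIC, BIC, silhouette, Davies–Bouldin and Calinski–Harabasz.
Representatives are the molecules nearest each centroid in the PCA space.

The quality indices are computed from their defining formulas (the K-means
objective WCSS, a spherical-Gaussian log-likelihood for AIC/BIC, and the
classical silhouette/DB/CH definitions); scikit-learn's implementations are
used only as independent cross-checks in the test suite.
`KMeansClusterer` and `CorrelationFilter` are scikit-learn-compatible
estimators and compose with sklearn pipelines.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorMatrix",
    "PCAResult",
    "KMeansResult",
    "ClusterQuality",
    "RepresentativeSet",
    "KMeansClusterer",
    "CorrelationFilter",
    "clean_descriptors",
    "correlation_filter",
    "pca",
    "kmeans",
    "cluster_quality",
    "select_k",
    "centroid_distances",
    "select_representatives",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DescriptorMatrix:
    """Molecules × descriptors table (ids + optional SMILES + numeric values)."""

    ids: List[str]
    descriptor_names: List[str]
    values: np.ndarray
    smiles: Optional[List[str]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.descriptor_names)):
            raise ValueError("values shape does not match ids × descriptor_names")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return len(self.descriptor_names)

    @classmethod
    def from_csv(cls, path, smiles_column: Optional[str] = "smiles") -> "DescriptorMatrix":
        """First column = molecule id; optional SMILES and ground-truth label
        columns are carried out of the numeric block; rest numeric."""
        df = pd.read_csv(path)
        ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
        smiles = None
        if smiles_column and smiles_column in df.columns:
            smiles = df[smiles_column].astype(str).tolist()
            df = df.drop(columns=[smiles_column])
        if "true_label" in df.columns:  # synthetic-fixture ground truth
            df = df.drop(columns=["true_label"])
        return cls(ids=ids, descriptor_names=list(df.columns),
                   values=df.to_numpy(dtype=float), smiles=smiles,
                   provenance=str(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.descriptor_names)


@dataclass
class PCAResult:
    loadings: np.ndarray          # d × m
    explained_variance_ratio: np.ndarray
    scores: np.ndarray            # n × m
    m: int
    means: np.ndarray
    sds: np.ndarray


@dataclass
class KMeansResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    seed: Optional[int]
    n_init: int
    converged: bool


@dataclass
class ClusterQuality:
    k: int
    wcss: float
    sigma2: float
    log_likelihood: float
    n_parameters: int
    aic: float
    bic: float
    silhouette: Optional[float]
    silhouette_values: Optional[np.ndarray]
    davies_bouldin: Optional[float]
    calinski_harabasz: Optional[float]
    singleton_clusters: List[int] = field(default_factory=list)


@dataclass
class RepresentativeSet:
    per_cluster: Dict[int, List[Tuple[str, float]]]
    m_per_cluster: int
    total: int
    truncated_clusters: List[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cleaning and filtering


def clean_descriptors(dm: DescriptorMatrix) -> DescriptorMatrix:
    """Drop descriptor columns with any non-finite value or zero variance."""
    keep = []
    for j, name in enumerate(dm.descriptor_names):
        col = dm.values[:, j]
        if not np.all(np.isfinite(col)):
            logger.info("dropping %s: non-finite values", name)
        elif np.ptp(col) == 0.0:
            logger.info("dropping %s: zero variance", name)
        else:
            keep.append(j)
    if not keep:
        raise ValueError("all descriptor columns were dropped during cleaning")
    return DescriptorMatrix(
        ids=dm.ids,
        descriptor_names=[dm.descriptor_names[j] for j in keep],
        values=dm.values[:, keep],
        smiles=dm.smiles,
        provenance=dm.provenance,
    )


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Drop columns whose |Pearson r| with an already-kept column exceeds
    ``threshold`` (deterministic keep-first policy, column order)."""

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        kept: List[int] = []
        dropped: List[int] = []
        for j in range(X.shape[1]):
            redundant = False
            for i in kept:
                sd_i, sd_j = X[:, i].std(), X[:, j].std()
                if sd_i == 0 or sd_j == 0:
                    continue
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                if abs(r) > self.threshold:
                    redundant = True
                    break
            (dropped if redundant else kept).append(j)
        self.kept_indices_ = kept
        self.dropped_indices_ = dropped
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.kept_indices_]


def correlation_filter(dm: DescriptorMatrix,
                       threshold: float = 0.95) -> Tuple[DescriptorMatrix, List[str]]:
    """Apply :class:`CorrelationFilter` to a descriptor matrix."""
    filt = CorrelationFilter(threshold=threshold).fit(dm.values)
    dropped = [dm.descriptor_names[j] for j in filt.dropped_indices_]
    out = DescriptorMatrix(
        ids=dm.ids,
        descriptor_names=[dm.descriptor_names[j] for j in filt.kept_indices_],
        values=dm.values[:, filt.kept_indices_],
        smiles=dm.smiles,
        provenance=dm.provenance,
    )
    return out, dropped


# ---------------------------------------------------------------------------
# PCA


def pca(dm: Union[DescriptorMatrix, np.ndarray], m: Union[int, float] = 2) -> PCAResult:
    """PCA of the z-scored descriptor matrix.

    ``m`` is either a component count or a cumulative explained-variance
    target in (0, 1).  Sign convention: each component's largest-magnitude
    loading is positive.
    """
    from sklearn.decomposition import PCA as _SKPCA

    X = dm.values if isinstance(dm, DescriptorMatrix) else np.asarray(dm, dtype=float)
    n, d = X.shape
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero-variance column: clean the matrix first")
    Z = (X - means) / sds

    full = _SKPCA(n_components=min(n - 1, d), svd_solver="full").fit(Z)
    if isinstance(m, float):
        if not 0 < m < 1:
            raise ValueError("variance target must be in (0, 1)")
        m_kept = int(np.searchsorted(np.cumsum(full.explained_variance_ratio_), m) + 1)
    else:
        m_kept = int(m)
        if not 1 <= m_kept <= full.n_components_:
            raise ValueError(f"m={m_kept} outside [1, rank={full.n_components_}]")

    loadings = full.components_[:m_kept].T.copy()          # d × m
    scores = Z @ loadings                                   # n × m
    for j in range(m_kept):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=full.explained_variance_ratio_[:m_kept].copy(),
        scores=scores,
        m=m_kept,
        means=means,
        sds=sds,
    )


# ---------------------------------------------------------------------------
# K-means


def _wcss(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


def _kmeans_pp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(cdist(X, np.array(centers), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    for it in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        new = centers.copy()
        for j in range(centers.shape[0]):
            members = X[labels == j]
            if members.shape[0] == 0:
                # empty-cluster repair: reseed at the point farthest from its centroid
                far = np.argmax(d2.min(axis=1))
                new[j] = X[far]
            else:
                new[j] = members.mean(axis=0)
        shift = np.linalg.norm(new - centers, axis=1).max()
        centers = new
        if shift < tol:
            d2 = cdist(X, centers, "sqeuclidean")
            labels = d2.argmin(axis=1)
            return labels, centers, True
    d2 = cdist(X, centers, "sqeuclidean")
    return d2.argmin(axis=1), centers, False


class KMeansClusterer(BaseEstimator, ClusterMixin):
    """Lloyd's K-means with k-means++ seeding and multi-restart.

    Best of ``n_init`` restarts by within-cluster sum of squares (WCSS, the
    K-means objective); convergence when the maximum centroid shift drops
    below ``tol``; empty clusters reseeded at the farthest point.
    """

    def __init__(self, k: int = 5, random_state: Optional[int] = None,
                 n_init: int = 10, max_iter: int = 300, tol: float = 1e-8):
        self.k = k
        self.random_state = random_state
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds n={n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers = _kmeans_pp(X, self.k, rng)
            labels, centers, converged = _lloyd(X, centers, self.max_iter, self.tol)
            w = _wcss(X, labels, centers)
            if best is None or w < best[0]:
                best = (w, labels, centers, converged)
        self.inertia_, self.labels_, self.cluster_centers_, self.converged_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return cdist(X, self.cluster_centers_, "sqeuclidean").argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans(X: np.ndarray, k: int, seed: Optional[int] = None,
           n_init: int = 10) -> KMeansResult:
    """Functional wrapper over :class:`KMeansClusterer`."""
    est = KMeansClusterer(k=k, random_state=seed, n_init=n_init).fit(X)
    return KMeansResult(
        k=k, labels=est.labels_, centroids=est.cluster_centers_,
        wcss=float(est.inertia_), seed=seed, n_init=n_init,
        converged=bool(est.converged_),
    )


# ---------------------------------------------------------------------------
# quality indices


def cluster_quality(X: np.ndarray, km: KMeansResult,
                    sigma2_policy: str = "mle") -> ClusterQuality:
    """AIC/BIC, silhouette, Davies–Bouldin and Calinski–Harabasz for a fit.

    The log-likelihood is that of spherical Gaussians at the centroids with a
    shared variance; under the default MLE policy σ̂² = WCSS/(n·m), giving
    ln L̂ = −(n·m/2)(ln(2π σ̂²) + 1).  Parameter count p = k·m + 1 (centroids
    plus the shared variance), so BIC − AIC = p(ln n − 2) identically.
    Silhouette of a singleton-cluster point is defined as 0 (flagged).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    k = km.k
    labels, centroids = km.labels, km.centroids
    wcss = _wcss(X, labels, centroids)

    if sigma2_policy == "mle":
        sigma2 = wcss / (n * m)
    else:
        raise ValueError(f"unknown sigma2 policy {sigma2_policy!r}")
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    lnL = -(n * m / 2.0) * (np.log(2.0 * np.pi * sigma2) + 1.0)
    p = k * m + 1
    aic = 2 * p - 2 * lnL
    bic = p * np.log(n) - 2 * lnL

    sizes = np.bincount(labels, minlength=k)
    singletons = [int(j) for j in range(k) if sizes[j] == 1]

    sil = sil_vals = db = ch = None
    if k >= 2:
        D = cdist(X, X)
        sil_vals = np.zeros(n)
        for i in range(n):
            ci = labels[i]
            if sizes[ci] == 1:
                sil_vals[i] = 0.0
                continue
            a_i = D[i][labels == ci].sum() / (sizes[ci] - 1)
            b_i = min(D[i][labels == j].mean() for j in range(k) if j != ci and sizes[j] > 0)
            sil_vals[i] = (b_i - a_i) / max(a_i, b_i)
        sil = float(sil_vals.mean())

        sigma_i = np.array([
            np.linalg.norm(X[labels == j] - centroids[j], axis=1).mean() if sizes[j] else 0.0
            for j in range(k)
        ])
        cd = cdist(centroids, centroids)
        ratios = np.full((k, k), -np.inf)
        for i in range(k):
            for j in range(k):
                if i != j and cd[i, j] > 0:
                    ratios[i, j] = (sigma_i[i] + sigma_i[j]) / cd[i, j]
        db = float(np.mean(ratios.max(axis=1)))

        grand = X.mean(axis=0)
        tr_b = float((sizes * ((centroids - grand) ** 2).sum(axis=1)).sum())
        tr_w = wcss
        ch = float((tr_b / tr_w) * ((n - k) / (k - 1))) if tr_w > 0 else np.inf

    return ClusterQuality(
        k=k, wcss=wcss, sigma2=sigma2, log_likelihood=float(lnL),
        n_parameters=p, aic=float(aic), bic=float(bic),
        silhouette=sil, silhouette_values=sil_vals,
        davies_bouldin=db, calinski_harabasz=ch,
        singleton_clusters=singletons,
    )


@dataclass
class SelectKResult:
    chosen_k: int
    table: pd.DataFrame
    votes: Dict[str, int]
    weak_structure: bool  # silhouette < 0.3 at every k


def select_k(X: np.ndarray,
             k_range: Iterable[int] = range(2, 11),
             seed: Optional[int] = None,
             n_init: int = 10) -> SelectKResult:
    """Consensus cluster-number selection over a range of k.

    Runs K-means + quality indices per k; the chosen k is the mode of
    {argmin AIC, argmin BIC, argmin DB, argmax silhouette, argmax CH}, ties
    broken in favor of the BIC winner.  The full per-k table (including WCSS
    for elbow inspection) is returned.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = X.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")

    rows = []
    for k in ks:
        km = kmeans(X, k, seed=None if seed is None else seed + k, n_init=n_init)
        q = cluster_quality(X, km)
        rows.append({
            "k": k, "wcss": q.wcss, "aic": q.aic, "bic": q.bic,
            "silhouette": q.silhouette, "davies_bouldin": q.davies_bouldin,
            "calinski_harabasz": q.calinski_harabasz,
        })
    table = pd.DataFrame(rows).set_index("k")

    votes = {
        "aic": int(table["aic"].idxmin()),
        "bic": int(table["bic"].idxmin()),
        "davies_bouldin": int(table["davies_bouldin"].idxmin()),
        "silhouette": int(table["silhouette"].idxmax()),
        "calinski_harabasz": int(table["calinski_harabasz"].idxmax()),
    }
    counts = Counter(votes.values())
    top = max(counts.values())
    modal = sorted(k for k, c in counts.items() if c == top)
    chosen = votes["bic"] if votes["bic"] in modal else min(modal, key=lambda k: table.loc[k, "bic"])
    weak = bool((table["silhouette"] < 0.3).all())
    if weak:
        warnings.warn("weak cluster structure: silhouette < 0.3 at every k")
    return SelectKResult(chosen_k=chosen, table=table, votes=votes, weak_structure=weak)


# ---------------------------------------------------------------------------
# representative selection


def centroid_distances(scores: np.ndarray, km: KMeansResult) -> np.ndarray:
    """Euclidean distance of each point to its own cluster centroid."""
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.linalg.norm(X - km.centroids[km.labels], axis=1)


def select_representatives(km: KMeansResult,
                           distances: np.ndarray,
                           m_per_cluster: int = 4,
                           ids: Optional[Sequence[str]] = None) -> RepresentativeSet:
    """Per cluster, the ``m_per_cluster`` molecules nearest the centroid.

    Molecules are returned in increasing-distance order (input order breaks
    ties); clusters smaller than ``m_per_cluster`` return all their members
    and are flagged as truncated.
    """
    if m_per_cluster < 1:
        raise ValueError("m_per_cluster must be >= 1")
    distances = np.asarray(distances, dtype=float)
    names = list(ids) if ids is not None else [str(i) for i in range(distances.size)]
    per_cluster: Dict[int, List[Tuple[str, float]]] = {}
    truncated: List[int] = []
    total = 0
    for j in range(km.k):
        members = np.nonzero(km.labels == j)[0]
        order = members[np.argsort(distances[members], kind="stable")]
        chosen = order[:m_per_cluster]
        if members.size < m_per_cluster:
            truncated.append(j)
        per_cluster[j] = [(names[i], float(distances[i])) for i in chosen]
        total += len(chosen)
    return RepresentativeSet(per_cluster=per_cluster, m_per_cluster=m_per_cluster,
                             total=total, truncated_clusters=truncated)
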