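"""PCA, self-organizing map and elbow k-means classification of samples.

Samples are represented by the highest retained -10lgP score of each marker
(zero when undetected).  PCA (centred, unscaled — prcomp-style) serves
visualisation; an online Kohonen SOM trained on the centred features,
followed by elbow k-means over the SOM codebook vectors, provides the
clustering.  Unknown (e.g. archaeological) samples are projected onto the
reference system: best-matching unit in the trained SOM, then that node's
k-means cluster; they never influence training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .marker_db import MarkerDatabase
from .psm_model import Cohort, detection_matrix

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples x markers matrix of highest retained scores (0 = undetected)."""

    values: pd.DataFrame  # index sample_ids, columns marker_ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def feature_matrix(cohort: Cohort, db: MarkerDatabase) -> FeatureMatrix:
    """One feature per marker id: the max -10lgP score in each sample."""
    dm = detection_matrix(cohort, db, value_kind="max_score")
    return FeatureMatrix(dm.values.T.copy())


@dataclass
class PCAResult:
    """prcomp-style decomposition: scores = centred X @ loadings."""

    scores: np.ndarray                  # (n_samples, n_comp)
    loadings: np.ndarray                # (n_features, n_comp), orthonormal
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


def pca(X: FeatureMatrix | np.ndarray, center: bool = True,
        scale: bool = False) -> PCAResult:
    """Centred (optionally variance-scaled) SVD principal component analysis."""
    if isinstance(X, FeatureMatrix):
        arr = X.as_array()
        sample_ids, feature_names = X.sample_ids, X.marker_ids
    else:
        arr = np.asarray(X, dtype=float)
        sample_ids = [str(i) for i in range(arr.shape[0])]
        feature_names = [str(j) for j in range(arr.shape[1])]
    if arr.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = arr.mean(axis=0) if center else np.zeros(arr.shape[1])
    Xc = arr - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PCAResult(U * s, Vt.T, evr, mean, sample_ids, feature_names)


@dataclass
class SOMModel:
    """A trained square-grid SOM plus (optional) k-means node clusters."""

    rows: int
    cols: int
    codebooks: np.ndarray               # (rows*cols, n_features)
    iterations: int
    seed: int
    feature_names: list[str]
    mean: np.ndarray                    # training centring vector
    node_clusters: np.ndarray | None = None
    n_clusters: int | None = None

    def bmu(self, x: np.ndarray) -> int:
        """Index of the best-matching unit (Euclidean) for one centred vector."""
        d = np.linalg.norm(self.codebooks - x, axis=1)
        return int(np.argmin(d))

    def to_json(self) -> str:
        return json.dumps({
            "rows": self.rows, "cols": self.cols,
            "codebooks": self.codebooks.tolist(),
            "iterations": self.iterations, "seed": self.seed,
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "node_clusters": (None if self.node_clusters is None
                              else self.node_clusters.tolist()),
            "n_clusters": self.n_clusters,
        })

    @classmethod
    def from_json(cls, text: str) -> "SOMModel":
        d = json.loads(text)
        return cls(d["rows"], d["cols"], np.asarray(d["codebooks"], dtype=float),
                   d["iterations"], d["seed"], d["feature_names"],
                   np.asarray(d["mean"], dtype=float),
                   None if d["node_clusters"] is None
                   else np.asarray(d["node_clusters"], dtype=int),
                   d["n_clusters"])


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    return np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)


def som_train(X: FeatureMatrix | np.ndarray, grid: tuple[int, int] = (4, 4),
              iterations: int = 10_000, seed: int = 0,
              learning_rate: tuple[float, float] = (0.05, 0.01),
              radius: tuple[float, float] | None = None) -> SOMModel:
    """Train an online Kohonen SOM on the centred feature matrix.

    Each iteration presents one randomly drawn sample; its best-matching unit
    and Gaussian neighbourhood move toward it.  The learning rate decays
    linearly between the given endpoints and the neighbourhood radius from
    half the grid diagonal down to 1.  Deterministic for a fixed seed.
    """
    if isinstance(X, FeatureMatrix):
        arr = X.as_array()
        feature_names = X.marker_ids
    else:
        arr = np.asarray(X, dtype=float)
        feature_names = [str(j) for j in range(arr.shape[1])]
    if arr.shape[0] < 1:
        raise ValueError("SOM needs at least one sample")
    rows, cols = grid
    n_nodes = rows * cols
    mean = arr.mean(axis=0)
    Xc = arr - mean

    rng = np.random.default_rng(seed)
    # init: random data rows with small jitter so nodes start distinct
    idx = rng.integers(0, Xc.shape[0], size=n_nodes)
    scale = Xc.std() if Xc.std() > 0 else 1.0
    codebooks = Xc[idx] + rng.normal(0.0, 0.01 * scale, size=(n_nodes, Xc.shape[1]))

    coords = _grid_coords(rows, cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    lr0, lr1 = learning_rate
    if radius is None:
        r0 = 0.5 * float(np.hypot(rows - 1, cols - 1))
        r0 = max(r0, 1.0)
        r1 = 1.0
    else:
        r0, r1 = radius

    order = rng.integers(0, Xc.shape[0], size=iterations)
    for it in range(iterations):
        frac = it / max(iterations - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        sigma = r0 + (r1 - r0) * frac
        x = Xc[order[it]]
        bmu = int(np.argmin(((codebooks - x) ** 2).sum(axis=1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
        codebooks += (lr * h)[:, None] * (x - codebooks)

    return SOMModel(rows, cols, codebooks, iterations, seed, feature_names, mean)


def kmeans_elbow(codebooks: np.ndarray, k_max: int = 8, seed: int = 0,
                 ) -> tuple[int, np.ndarray]:
    """Pick k by the elbow of the within-cluster-SS curve and return k plus
    the node cluster labels.

    The elbow is the k maximising the second difference of log WCSS — the
    scale-free form of the maximal-curvature rule.  (The raw second
    difference systematically favours k=2 on geometrically decaying curves.)
    """
    cb = np.asarray(codebooks, dtype=float)
    n_distinct = np.unique(cb, axis=0).shape[0]
    k_max = min(k_max, cb.shape[0])
    wcss: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k > n_distinct:
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(cb)
        wcss[k] = float(km.inertia_)
        labels[k] = km.labels_.copy()
    ks = sorted(wcss)
    if len(ks) == 1 or wcss[ks[0]] <= 1e-12:
        return 1, np.zeros(cb.shape[0], dtype=int)
    floor = 1e-12 * max(wcss[ks[0]], 1.0)
    logw = {k: np.log(max(wcss[k], floor)) for k in ks}
    best_k, best_dd = ks[0], -np.inf
    for k in ks[1:-1]:
        dd = logw[k - 1] - 2.0 * logw[k] + logw[k + 1]
        if dd > best_dd:
            best_k, best_dd = k, dd
    if len(ks) == 2:  # no interior point: choose the larger k if it helps
        best_k = ks[1] if wcss[ks[1]] < 0.5 * wcss[ks[0]] else ks[0]
    return best_k, labels[best_k]


def cluster_som(model: SOMModel, k_max: int = 8, seed: int = 0) -> SOMModel:
    """Attach elbow k-means node clusters to a trained SOM."""
    k, labels = kmeans_elbow(model.codebooks, k_max=k_max, seed=seed)
    model.node_clusters = labels
    model.n_clusters = k
    return model


def _align_features(new: FeatureMatrix, feature_names: list[str]) -> pd.DataFrame:
    unknown = set(new.marker_ids) - set(feature_names)
    if unknown:
        raise ValueError(
            f"query samples carry unknown markers: {sorted(unknown)[:10]}")
    missing = [f for f in feature_names if f not in new.values.columns]
    if missing:
        logger.warning("query missing %d marker columns; zero-filled", len(missing))
    return new.values.reindex(columns=feature_names, fill_value=0.0)


def classify_new(model: SOMModel, pca_basis: PCAResult, new: FeatureMatrix,
                 ) -> pd.DataFrame:
    """Assign query samples to the reference SOM/k-means clusters.

    Returns a table with the BMU node, its cluster label, the PCA projection
    coordinates, and a low-information flag for all-zero feature vectors.
    """
    if model.node_clusters is None:
        raise ValueError("SOM has no k-means node clusters; run cluster_som first")
    aligned = _align_features(new, model.feature_names)
    arr = aligned.to_numpy(dtype=float)
    proj = pca_basis.project(arr)
    rows = []
    for i, sid in enumerate(aligned.index):
        x = arr[i] - model.mean
        bmu = model.bmu(x)
        rows.append({
            "sample": sid,
            "bmu": bmu,
            "cluster": int(model.node_clusters[bmu]),
            "PC1": float(proj[i, 0]) if proj.shape[1] > 0 else 0.0,
            "PC2": float(proj[i, 1]) if proj.shape[1] > 1 else 0.0,
            "low_information": bool(not np.any(arr[i])),
        })
    return pd.DataFrame(rows)


def sample_clusters(model: SOMModel, X: FeatureMatrix) -> pd.Series:
    """Cluster label of each sample in X (BMU -> node cluster)."""
    if model.node_clusters is None:
        raise ValueError("SOM has no k-means node clusters; run cluster_som first")
    aligned = _align_features(X, model.feature_names)
    arr = aligned.to_numpy(dtype=float) - model.mean
    labels = [int(model.node_clusters[model.bmu(x)]) for x in arr]
    return pd.Series(labels, index=aligned.index, name="cluster")
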