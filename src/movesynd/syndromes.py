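"""Movement-syndrome detection: PCA, k-means, and silhouette-based k.

The input is the z-scored n_i x 23 residual matrix (16 residual movement
statistics plus 7 posterior-mean movement parameters).  PCA summarizes the
correlated variation; k-means splits individuals into syndromes; the
number of clusters is chosen by the Average Silhouette Method.  Cluster
labels are canonicalized by sorting centroids on their first coordinate so
runs are label-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


@dataclass
class SyndromeResult:
    loadings: np.ndarray  # (p, n_comp) orthonormal columns
    scores: np.ndarray  # (n_i, n_comp)
    variance_fraction: np.ndarray
    assignments: np.ndarray  # cluster label per individual, 1..k
    k: int
    silhouette: pd.Series  # mean silhouette width per candidate k
    centroids: np.ndarray  # (k, p) in the input space
    columns: list[str]


def pca(matrix: np.ndarray, center: bool = True):
    """Principal components: (loadings, scores, variance fractions).

    Columns are centred (inputs are typically z-scored already); loadings
    are orthonormal, scores the projections, variance fractions sum to 1
    and are nonincreasing.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix has no principal components")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X if not center else X - X.mean(axis=0))
    loadings = model.components_.T
    frac = model.explained_variance_ratio_
    # PCA truncates zero-variance trailing components only at n_comp; the
    # retained fractions are renormalized over all variance present
    return loadings, scores, frac


def kmeans_fit(matrix: np.ndarray, k: int, seed: int = 0, n_starts: int = 50):
    """Best-of-restarts k-means: (assignments 1..k, centroids, within-SS)."""
    X = np.asarray(matrix, dtype=float)
    if k >= X.shape[0]:
        raise ValueError(f"k = {k} must be smaller than the number of rows {X.shape[0]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[raw]
    centroids = np.stack([X[assignments == c].mean(axis=0) for c in range(1, k + 1)])
    within_ss = float(km.inertia_)
    return assignments, centroids, within_ss


def select_k(matrix: np.ndarray, k_range=range(2, 9), seed: int = 0, n_starts: int = 50):
    """Average Silhouette Method: the k maximizing mean silhouette width.

    Ties go to the smallest k; any k producing an empty or singleton-only
    degenerate clustering is skipped with a warning.  Returns
    ``(k, silhouette_series)``.
    """
    X = np.asarray(matrix, dtype=float)
    sil = {}
    for k in k_range:
        if not (2 <= k < X.shape[0]):
            continue
        try:
            assignments, _, _ = kmeans_fit(X, k, seed=seed, n_starts=n_starts)
            if len(np.unique(assignments)) < k:
                warnings.warn(f"k = {k}: empty cluster, skipped")
                continue
            sil[k] = float(silhouette_score(X, assignments, metric="euclidean"))
        except ValueError as err:
            warnings.warn(f"k = {k} skipped: {err}")
    if not sil:
        raise ValueError("no candidate k could be evaluated")
    series = pd.Series(sil).sort_index()
    best = series.index[np.argmax(series.to_numpy())]
    return int(best), series


def detect_syndromes(
    matrix: pd.DataFrame | np.ndarray,
    k_range=range(2, 9),
    seed: int = 0,
    n_starts: int = 50,
    k: int | None = None,
) -> SyndromeResult:
    """Full syndrome analysis of a normalized residual matrix."""
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        columns = [f"V{i+1}" for i in range(X.shape[1])]
    loadings, scores, frac = pca(X)
    if k is None:
        k, sil = select_k(X, k_range=k_range, seed=seed, n_starts=n_starts)
    else:
        _, sil = select_k(X, k_range=k_range, seed=seed, n_starts=n_starts)
    assignments, centroids, _ = kmeans_fit(X, k, seed=seed, n_starts=n_starts)
    return SyndromeResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=frac,
        assignments=assignments,
        k=k,
        silhouette=sil,
        centroids=centroids,
        columns=columns,
    )


def centroid_table(result: SyndromeResult) -> pd.DataFrame:
    """Cluster centroids over the input columns (one row per syndrome)."""
    df = pd.DataFrame(result.centroids, columns=result.columns)
    df.insert(0, "cluster", np.arange(1, result.k + 1))
    return df.set_index("cluster")


def biplot(result: SyndromeResult, path, title: str = "Movement syndromes") -> None:
    """Scatter of PC1/PC2 scores coloured by cluster, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for c in range(1, result.k + 1):
        sel = result.assignments == c
        ax.scatter(result.scores[sel, 0], result.scores[sel, 1], label=f"syndrome {c}")
    ax.set_xlabel(f"PC1 ({100 * result.variance_fraction[0]:.1f} %)")
    ax.set_ylabel(f"PC2 ({100 * result.variance_fraction[1]:.1f} %)")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
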