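"""Density-based clustering and PCA biplots of ionomes in clr space.

Because the Aitchison distance between compositions equals the Euclidean
distance between their clr images, ordinary DBSCAN and PCA applied to the
clr matrix operate directly in the natural geometry of the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

__all__ = ["ClusterResult", "BiplotResult", "dbscan_cluster", "suggest_eps",
           "pca_biplot", "plot_biplot"]

NOISE = -1


@dataclass(frozen=True)
class ClusterResult:
    """DBSCAN labels over the records of a clr matrix.

    ``labels`` holds a cluster id per row, with −1 marking noise points.
    """

    labels: np.ndarray
    eps: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def n_noise(self) -> int:
        return int((self.labels == NOISE).sum())


@dataclass(frozen=True)
class BiplotResult:
    """PCA of a clr matrix with the two standard biplot scalings.

    ``scores`` are row coordinates in distance scaling (principal
    coordinates; their pairwise Euclidean distances reproduce the
    Aitchison distances when every component is retained). ``loadings``
    are the correlations of each clr variable with each component
    (correlation scaling).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    columns: tuple[str, ...]
    dropped_columns: tuple[str, ...] = field(default=())


def dbscan_cluster(clr: np.ndarray, eps: float, min_pts: int = 7) -> ClusterResult:
    """Density-based clustering of clr vectors (Euclidean = Aitchison metric).

    A point with at least ``min_pts`` neighbours within ``eps`` (itself
    included) is a core point; clusters are the connected components of
    density-reachability; non-core points not reachable from any core point
    are labelled noise (−1). Deterministic given row order.
    """
    clr = np.asarray(clr, dtype=float)
    if clr.size == 0:
        raise ValueError("empty clr matrix")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be at least 2")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(clr).labels_
    return ClusterResult(labels=labels, eps=float(eps), min_pts=int(min_pts))


def suggest_eps(clr: np.ndarray, min_pts: int = 7) -> tuple[float, np.ndarray]:
    """Choose eps from the knee of the sorted k-nearest-neighbour curve.

    For each row the distance to its (min_pts − 1)-th nearest neighbour is
    computed (so a core point at the suggested eps has min_pts points in
    its neighbourhood, itself included); the distances are sorted
    ascending, and the knee is the point of maximum deviation from the
    chord joining the curve's endpoints. On a flat curve (all distances
    equal) the common distance itself is returned.

    Returns the suggested eps and the sorted distance curve for inspection.
    """
    clr = np.asarray(clr, dtype=float)
    n = clr.shape[0]
    if n <= min_pts:
        raise ValueError("need more rows than min_pts")
    k = min_pts - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(clr)
    dist, _ = nn.kneighbors(clr)
    curve = np.sort(dist[:, k])
    if curve[-1] - curve[0] < 1e-12 or curve.size < 3:
        return float(curve[-1]), curve
    # perpendicular distance of each curve point to the endpoint chord
    x = np.arange(curve.size, dtype=float)
    x0, y0, x1, y1 = x[0], curve[0], x[-1], curve[-1]
    num = np.abs((y1 - y0) * x - (x1 - x0) * curve + x1 * y0 - y1 * x0)
    knee = int(np.argmax(num))
    return float(curve[knee]), curve


def pca_biplot(clr: np.ndarray, columns: tuple[str, ...] | None = None) -> BiplotResult:
    """Principal component analysis of a clr matrix for biplot display.

    Columns are centred; constant columns are excluded with a warning.
    Scores are U·S from the SVD of the centred matrix (distance scaling);
    loadings are Pearson correlations between each retained clr variable
    and each score column (correlation scaling). Components with zero
    singular value are dropped.
    """
    clr = np.asarray(clr, dtype=float)
    if clr.shape[0] < 3:
        raise ValueError("need at least 3 rows for a PCA biplot")
    if columns is None:
        columns = tuple(f"var{i}" for i in range(clr.shape[1]))
    columns = tuple(columns)

    sd = clr.std(axis=0)
    keep = sd > 1e-12
    dropped = tuple(c for c, k in zip(columns, keep) if not k)
    if dropped:
        warnings.warn(f"constant clr columns excluded from PCA: {dropped}")
    kept_cols = tuple(c for c, k in zip(columns, keep) if k)
    x = clr[:, keep]
    x = x - x.mean(axis=0)

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    nz = s > max(s[0], 1.0) * 1e-12 if s.size else np.array([], bool)
    u, s = u[:, nz], s[nz]
    scores = u * s
    var = s**2 / (x.shape[0] - 1)
    ratio = var / (x.var(axis=0, ddof=1).sum())

    loadings = np.empty((x.shape[1], scores.shape[1]))
    for j in range(scores.shape[1]):
        sc = scores[:, j]
        sc_sd = sc.std(ddof=1)
        for i in range(x.shape[1]):
            loadings[i, j] = np.corrcoef(x[:, i], sc)[0, 1] if sc_sd > 0 else 0.0
    return BiplotResult(
        scores=scores, loadings=loadings,
        explained_variance_ratio=ratio,
        columns=kept_cols, dropped_columns=dropped,
    )


def plot_biplot(result: BiplotResult, ax=None, n_points: int | None = 2000):
    """Render the score/loading biplot with matplotlib (optional extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pts = result.scores
    if n_points is not None and pts.shape[0] > n_points:
        pts = pts[:n_points]
    ax.scatter(pts[:, 0], pts[:, 1], s=6, alpha=0.4, color="grey")
    scale = np.abs(pts[:, :2]).max()
    for name, (lx, ly) in zip(result.columns, result.loadings[:, :2]):
        ax.annotate(name, (lx * scale, ly * scale), color="firebrick")
        ax.plot([0, lx * scale], [0, ly * scale], color="firebrick", lw=0.8)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    return ax
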