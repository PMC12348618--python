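"""BMI-trajectory clustering: correlation similarity of 6-point monthly BMI
series, average-linkage (UPGMA) hierarchical clustering, internal validity
indices over candidate cluster counts, and trajectory-type contrasts.

Similarity between two subjects is the Pearson correlation of their
within-subject mean-removed 6-point series (so a vertical BMI offset does
not affect shape similarity); clustering distance is 1 − r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .association import group_compare

log = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    labels: np.ndarray
    merges: np.ndarray  # scipy linkage matrix
    k: int
    db_by_k: dict[int, float]
    ch_by_k: dict[int, float]
    kept: np.ndarray    # subjects retained (non-constant trajectories)


def center_rows(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    return M - M.mean(axis=1, keepdims=True)


def trajectory_similarity(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x subjects Pearson correlation of centered trajectories.

    Constant trajectories are excluded (warning).  Returns (correlation
    matrix, kept-subject index array).
    """
    M = np.asarray(M, float)
    if M.ndim != 2:
        raise ValueError("expect a subjects x timepoints matrix")
    sd = M.std(axis=1)
    kept = np.nonzero(sd > 0)[0]
    if len(kept) < M.shape[0]:
        log.warning("excluding %d constant trajectory(ies)",
                    M.shape[0] - len(kept))
    corr = np.corrcoef(center_rows(M[kept]))
    return corr, kept


def hclust_average(distance: np.ndarray) -> np.ndarray:
    """UPGMA merge structure for a symmetric zero-diagonal distance matrix."""
    D = np.asarray(distance, float)
    if np.isnan(D).any():
        raise ValueError("NaN distances")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return linkage(squareform(D, checks=False), method="average")


def cut_dendrogram(merges: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the dendrogram at k clusters."""
    return fcluster(merges, t=k, criterion="maxclust")


def cluster_indices(points: np.ndarray, merges: np.ndarray,
                    k_range=range(2, 6)) -> tuple[dict[int, float],
                                                  dict[int, float]]:
    """Davies–Bouldin and Calinski–Harabasz curves over cluster counts,
    computed on the clustering's feature space (centered trajectories)."""
    points = np.asarray(points, float)
    n = len(points)
    db, ch = {}, {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError("k_range must lie within [2, n-1]")
        labels = cut_dendrogram(merges, k)
        if np.unique(labels).size < 2:
            db[k] = float("nan")
            ch[k] = float("nan")
            continue
        db[k] = float(davies_bouldin_score(points, labels))
        ch[k] = float(calinski_harabasz_score(points, labels))
    return db, ch


def cluster_trajectories(M: np.ndarray, k: int = 2,
                         k_range=range(2, 6)) -> ClusteringResult:
    """Full pipeline: similarity -> UPGMA -> cut at k, with index curves."""
    corr, kept = trajectory_similarity(M)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    merges = hclust_average(dist)
    centered = center_rows(np.asarray(M, float)[kept])
    db, ch = cluster_indices(centered, merges, k_range)
    labels = cut_dendrogram(merges, k)
    return ClusteringResult(labels=labels, merges=merges, k=k,
                            db_by_k=db, ch_by_k=ch, kept=kept)


def compare_types(expression: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, float]:
    """Two-sample t-test of state expression between the two trajectory
    types (label order: first cluster vs second)."""
    expression = np.asarray(expression, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("expect exactly two trajectory types")
    a = expression[labels == uniq[0]]
    b = expression[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each type needs at least two members")
    return group_compare(a, b)
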