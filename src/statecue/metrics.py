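"""Comparison metrics for state labelings and state activation maps.

zRand standardizes the count of co-assigned pairs against its exact mean and
variance under the permutation (hypergeometric) null over the two labelings'
margins; NMI normalizes mutual information by the arithmetic mean of
entropies; state matching solves the optimal one-to-one assignment between
two sets of activation maps and reports the mean matched correlation
(activity concordance index).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score


def _pair_moments(labels: np.ndarray) -> tuple[float, float, float]:
    """(M1, T, Q): co-clustered pair count, ordered pair-of-pairs sharing one
    node, ordered disjoint pair-of-pairs, for one labeling."""
    _, counts = np.unique(labels, return_counts=True)
    c = counts.astype(float)
    M1 = float((c * (c - 1)).sum() / 2.0)
    T3 = float((c * (c - 1) * (c - 2)).sum())
    Q = M1 * M1 - M1 - T3
    return M1, T3, Q


def zrand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Standardized pair-counting agreement between two labelings.

    Let w be the number of node pairs placed together in both labelings.
    Under random permutation of one labeling, E[w] and Var[w] follow from
    the margins alone; zRand = (w - E[w]) / sd(w).  Invariant to label
    renaming and symmetric in its arguments.  Returns NaN (flagged
    undefined) when either side is a single cluster, where the null
    variance is zero.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("labelings must share a length >= 2")
    n = a.size
    M = n * (n - 1) / 2.0

    # contingency-based count of pairs together in both labelings
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    w = float((cont * (cont - 1)).sum() / 2.0)

    M1, Ta, Qa = _pair_moments(a)
    M2, Tb, _ = _pair_moments(b)
    if M1 in (0.0, M) or M2 in (0.0, M):
        return float("nan")  # single-cluster (or all-singleton) side: null variance 0

    p2 = M2 / M
    mean_w = M1 * p2

    # P(two B-pairs sharing a node are both co-clustered) and the 4-distinct-
    # node analogue, from the B margins.
    _, counts_b = np.unique(b, return_counts=True)
    cb = counts_b.astype(float)
    p3 = (cb * (cb - 1) * (cb - 2)).sum() / (n * (n - 1) * (n - 2))
    s2 = (cb * (cb - 1)).sum()
    quad = ((cb * (cb - 1) * (cb - 2) * (cb - 3)).sum()
            + s2 * s2 - ((cb * (cb - 1)) ** 2).sum())
    p4 = quad / (n * (n - 1) * (n - 2) * (n - 3)) if n > 3 else 0.0

    var_w = (M1 * (p2 - p2 * p2)
             + Ta * (p3 - p2 * p2)
             + Qa * (p4 - p2 * p2))
    if var_w <= 0:
        return float("nan")
    return (w - mean_w) / np.sqrt(var_w)


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalization).

    A constant labeling carries no information: returns 0 if either side has
    a single unique label (scikit-learn's convention of 1 for two constant
    labelings is deliberately overridden).
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must share a length")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def match_states(maps_a: np.ndarray, maps_b: np.ndarray
                 ) -> tuple[np.ndarray, float]:
    """Optimal one-to-one matching of K x P activation maps.

    Maximizes the summed Pearson correlation between matched rows (Hungarian
    algorithm).  Returns (permutation, concordance): ``permutation[i]`` is
    the row of ``maps_b`` matched to row i of ``maps_a``; concordance is the
    mean matched correlation.
    """
    A = np.asarray(maps_a, float)
    B = np.asarray(maps_b, float)
    if A.shape != B.shape:
        raise ValueError("map sets must share shape (K x P)")
    K = A.shape[0]
    sim = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            sa, sb = A[i].std(), B[j].std()
            sim[i, j] = (np.corrcoef(A[i], B[j])[0, 1]
                         if sa > 0 and sb > 0 else 0.0)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    concordance = float(sim[rows, cols].mean())
    return perm, concordance
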