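"""Gaussian hidden Markov model on PCA-reduced parcel time series.

States carry a full-covariance Gaussian emission in PC space and switch with
first-order Markov dynamics.  Training is EM (Baum–Welch) with k-means
initialization and multiple restarts; concatenated subjects/runs are treated
as independent chains (the forward–backward recursions restart with the
initial distribution at every sequence boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Standardization and PCA reduction
# ---------------------------------------------------------------------------

def standardize(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column-wise z-score of a T x P series (sample SD by default)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two time points to standardize")
    sd = X.std(axis=0, ddof=ddof)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant parcel column(s): {bad.tolist()}")
    return (X - X.mean(axis=0)) / sd


@dataclass
class PCAProjection:
    mean_vector: np.ndarray
    components: np.ndarray       # P x D loading matrix
    explained_ratio: np.ndarray  # D fractions, nonincreasing
    var_threshold: float | None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_vector) @ self.components

    def inverse_transform(self, Y: np.ndarray) -> np.ndarray:
        return np.asarray(Y, float) @ self.components.T + self.mean_vector


def pca_fit(X_concat: np.ndarray, var_threshold: float | None = 0.9,
            n_components: int | None = None) -> PCAProjection:
    """Fit a PCA projection keeping the smallest D whose cumulative explained
    variance reaches ``var_threshold`` (or exactly ``n_components``)."""
    if n_components is not None:
        model = PCA(n_components=n_components)
    else:
        if not 0.0 < var_threshold <= 1.0:
            raise ValueError("var_threshold must lie in (0, 1]")
        # sklearn's float n_components picks the smallest D with
        # cumulative explained variance >= threshold.
        model = PCA(n_components=var_threshold if var_threshold < 1.0 else None,
                    svd_solver="full")
    model.fit(np.asarray(X_concat, float))
    return PCAProjection(mean_vector=model.mean_,
                         components=model.components_.T,
                         explained_ratio=model.explained_variance_ratio_,
                         var_threshold=var_threshold if n_components is None else None)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    K: int
    initial: np.ndarray       # K simplex
    transitions: np.ndarray   # K x K row-stochastic
    means: np.ndarray         # K x D
    covariances: np.ndarray   # K x D x D, SPD
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class StatePath:
    gamma: np.ndarray    # T x K posterior state probabilities
    viterbi: np.ndarray  # T-vector of hard states in {0..K-1}


# ---------------------------------------------------------------------------
# Emission likelihoods
# ---------------------------------------------------------------------------

def _chol_factors(covariances: np.ndarray, reg: float = 1e-6
                  ) -> list[np.ndarray]:
    """Cholesky factors per state, adding diagonal ridge on failure."""
    factors = []
    for k, cov in enumerate(covariances):
        try:
            factors.append(linalg.cholesky(cov, lower=True))
        except linalg.LinAlgError:
            log.warning("covariance of state %d not SPD; adding %g ridge", k, reg)
            jitter = reg
            for _ in range(10):
                try:
                    factors.append(linalg.cholesky(
                        cov + jitter * np.eye(cov.shape[0]), lower=True))
                    break
                except linalg.LinAlgError:
                    jitter *= 10.0
            else:
                raise linalg.LinAlgError(
                    f"state {k} covariance could not be regularized")
    return factors


def _log_emissions(Y: np.ndarray, means: np.ndarray,
                   covariances: np.ndarray) -> np.ndarray:
    """T x K matrix of Gaussian log densities."""
    T, D = Y.shape
    K = means.shape[0]
    out = np.empty((T, K))
    for k, L in enumerate(_chol_factors(covariances)):
        diff = Y - means[k]
        sol = linalg.solve_triangular(L, diff.T, lower=True)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (D * _LOG2PI + logdet + maha)
    return out


# ---------------------------------------------------------------------------
# Forward–backward and Viterbi (scaled / log-space)
# ---------------------------------------------------------------------------

def _forward_backward(logB: np.ndarray, initial: np.ndarray,
                      transitions: np.ndarray):
    """Scaled forward–backward for one sequence.

    Returns (loglik, gamma T x K, xi_sum K x K, gamma0 K).
    """
    T, K = logB.shape
    bmax = logB.max(axis=1)
    Bs = np.exp(logB - bmax[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * Bs[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transitions) * Bs[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + bmax.sum())

    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = Bs[t + 1] * beta[t + 1]
        beta[t] = (transitions @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * transitions
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum, gamma[0]


def _forward_backward_batch(logB: np.ndarray, initial: np.ndarray,
                            transitions: np.ndarray):
    """Scaled forward–backward over a stack of equal-length sequences.

    ``logB`` is S x T x K.  Returns per-sequence (loglik S, gamma S x T x K,
    xi_sum S x K x K, gamma0 S x K).  Identical recursions to
    :func:`_forward_backward`, vectorized across the sequence axis.
    """
    S, T, K = logB.shape
    bmax = logB.max(axis=2)
    Bs = np.exp(logB - bmax[..., None])

    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = initial * Bs[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ transitions) * Bs[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = np.log(c).sum(axis=1) + bmax.sum(axis=1)

    beta = np.empty((S, T, K))
    beta[:, -1] = 1.0
    xi_sum = np.zeros((S, K, K))
    for t in range(T - 2, -1, -1):
        bb = Bs[:, t + 1] * beta[:, t + 1]
        scaled = bb / c[:, t + 1, None]
        beta[:, t] = scaled @ transitions.T
        xi_sum += alpha[:, t, :, None] * scaled[:, None, :] * transitions
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return loglik, gamma, xi_sum, gamma[:, 0]


def _viterbi(logB: np.ndarray, initial: np.ndarray,
             transitions: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        log_init = np.log(initial)
        log_trans = np.log(transitions)
    delta = log_init + logB[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _split(Y: np.ndarray, lengths: list[int] | None):
    if lengths is None:
        return [Y]
    if sum(lengths) != len(Y):
        raise ValueError("sequence lengths do not sum to the data length")
    out, start = [], 0
    for n in lengths:
        out.append(Y[start:start + n])
        start += n
    return out


# ---------------------------------------------------------------------------
# EM training
# ---------------------------------------------------------------------------

def hmm_fit(Y: np.ndarray, K: int, lengths: list[int] | None = None,
            seed: int = 0, n_restarts: int = 5, max_iter: int = 100,
            tol: float = 1e-5, reg: float = 1e-6) -> HMMParams:
    """Fit a K-state full-covariance Gaussian HMM by EM, best of restarts.

    ``tol`` is the per-frame log-likelihood improvement below which EM stops.
    Each restart initializes means by k-means, covariances by cluster
    scatter, transitions with 0.9 self-transition, uniform initial.
    """
    Y = np.asarray(Y, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    seqs = _split(Y, lengths)
    best: HMMParams | None = None
    best_ll = -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        params = _em_once(Y, seqs, K, restart_seed, max_iter, tol, reg)
        if params.loglik_trace[-1] > best_ll:
            best_ll = params.loglik_trace[-1]
            best = params
    return best


def _init_params(Y: np.ndarray, K: int, seed: int, reg: float) -> HMMParams:
    D = Y.shape[1]
    global_cov = np.cov(Y.T).reshape(D, D) + reg * np.eye(D)
    if K == 1:
        means = Y.mean(axis=0, keepdims=True)
        covs = global_cov[None]
    else:
        km = KMeans(n_clusters=K, n_init=3, random_state=seed).fit(Y)
        means = km.cluster_centers_
        covs = np.empty((K, D, D))
        for k in range(K):
            sel = Y[km.labels_ == k]
            if len(sel) > D:
                covs[k] = np.cov(sel.T).reshape(D, D) + reg * np.eye(D)
            else:
                covs[k] = global_cov
    trans = np.full((K, K), (0.1 / (K - 1)) if K > 1 else 0.0)
    np.fill_diagonal(trans, 0.9 if K > 1 else 1.0)
    return HMMParams(K=K, initial=np.full(K, 1.0 / K), transitions=trans,
                     means=means, covariances=covs)


def _em_once(Y: np.ndarray, seqs: list[np.ndarray], K: int, seed: int,
             max_iter: int, tol: float, reg: float) -> HMMParams:
    n_frames, D = Y.shape
    params = _init_params(Y, K, seed, reg)
    global_cov = np.cov(Y.T).reshape(D, D) + reg * np.eye(D)
    rng = np.random.default_rng(seed)
    trace = []
    prev_ll = -np.inf
    # group equal-length sequences so forward-backward can run batched
    offsets = np.concatenate([[0], np.cumsum([len(S) for S in seqs])])
    by_length: dict[int, list[int]] = {}
    for i, S in enumerate(seqs):
        by_length.setdefault(len(S), []).append(i)

    for _ in range(max_iter):
        # E-step
        logB_full = _log_emissions(Y, params.means, params.covariances)
        ll = 0.0
        xi_sum = np.zeros((K, K))
        init_sum = np.zeros(K)
        gamma_full = np.empty((n_frames, K))
        for T_len, idxs in by_length.items():
            stack = np.stack([logB_full[offsets[i]:offsets[i + 1]]
                              for i in idxs])
            lls, gammas, xis, g0s = _forward_backward_batch(
                stack, params.initial, params.transitions)
            ll += float(lls.sum())
            xi_sum += xis.sum(axis=0)
            init_sum += g0s.sum(axis=0)
            for j, i in enumerate(idxs):
                gamma_full[offsets[i]:offsets[i + 1]] = gammas[j]
        gamma_sum = gamma_full.sum(axis=0)
        trace.append(ll)

        # M-step
        safe = np.maximum(gamma_sum, 1e-12)
        means = (gamma_full.T @ Y) / safe[:, None]
        covs = np.empty((K, D, D))
        for k in range(K):
            diff = Y - means[k]
            covs[k] = (gamma_full[:, k, None] * diff).T @ diff
        covs /= safe[:, None, None]
        covs += reg * np.eye(D)
        for k in range(K):
            if gamma_sum[k] < 1.0:  # starved state: reseed on a random frame
                log.warning("state %d starved; reseeding", k)
                means[k] = Y[rng.integers(0, n_frames)]
                covs[k] = global_cov
        if K > 1:
            row = xi_sum.sum(axis=1, keepdims=True)
            transitions = np.where(row > 0, xi_sum / np.maximum(row, 1e-300),
                                   1.0 / K)
        else:
            transitions = np.ones((1, 1))
        initial = init_sum / init_sum.sum()
        params = HMMParams(K=K, initial=initial, transitions=transitions,
                           means=means, covariances=covs)

        if ll - prev_ll < tol * n_frames and np.isfinite(prev_ll):
            break
        prev_ll = ll
    params.loglik_trace = np.asarray(trace)
    return params


def hmm_loglik(params: HMMParams, Y: np.ndarray,
               lengths: list[int] | None = None) -> float:
    """Total forward-algorithm log-likelihood of ``Y`` under ``params``."""
    total = 0.0
    for S in _split(np.asarray(Y, float), lengths):
        logB = _log_emissions(S, params.means, params.covariances)
        ll, *_ = _forward_backward(logB, params.initial, params.transitions)
        total += ll
    return total


def hmm_decode(params: HMMParams, Y: np.ndarray,
               lengths: list[int] | None = None) -> StatePath:
    """Posterior (forward–backward) and Viterbi state assignments."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != params.means.shape[1]:
        raise ValueError("data dimensionality does not match the model")
    gammas, paths = [], []
    for S in _split(Y, lengths):
        logB = _log_emissions(S, params.means, params.covariances)
        _, gamma, _, _ = _forward_backward(logB, params.initial,
                                           params.transitions)
        gammas.append(gamma)
        paths.append(_viterbi(logB, params.initial, params.transitions))
    return StatePath(gamma=np.vstack(gammas), viterbi=np.concatenate(paths))


# ---------------------------------------------------------------------------
# Fractional occupancy
# ---------------------------------------------------------------------------

def fractional_occupancy(path: StatePath | np.ndarray, K: int,
                         interval: tuple[int, int] | None = None,
                         soft: bool = False) -> np.ndarray:
    """Proportion of TRs each state occupies within ``interval`` [start, end).

    Hard Viterbi counts by default; ``soft=True`` averages the posterior.
    """
    if isinstance(path, StatePath):
        labels, gamma = path.viterbi, path.gamma
    else:
        labels, gamma = np.asarray(path, int), None
        if soft:
            raise ValueError("soft occupancy needs a StatePath with gamma")
    start, end = (0, len(labels)) if interval is None else interval
    if not 0 <= start < end <= len(labels):
        raise ValueError("empty or out-of-range interval")
    if soft:
        return gamma[start:end].mean(axis=0)
    return np.bincount(labels[start:end], minlength=K) / (end - start)
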