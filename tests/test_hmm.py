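"""HMM core: oracle equivalences (path enumeration, hmmlearn), EM contracts,
PCA reduction, fractional occupancy."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from statecue.hmm import (HMMParams, StatePath, fractional_occupancy,
                          hmm_decode, hmm_fit, hmm_loglik, pca_fit,
                          standardize)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _random_params(rng, K, D, spread=4.0):
    means = rng.normal(0, spread, size=(K, D))
    covs = np.empty((K, D, D))
    for k in range(K):
        A = rng.normal(size=(D, D))
        covs[k] = A @ A.T + np.eye(D)
    trans = rng.random((K, K)) + 0.1
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.random(K) + 0.1
    init /= init.sum()
    return HMMParams(K=K, initial=init, transitions=trans, means=means,
                     covariances=covs)


def _enumerate_paths(params, Y):
    """Brute-force joint likelihood over all K^T paths.

    Returns (loglik, gamma) computed by exhaustive summation.
    """
    T = len(Y)
    K = params.K
    dens = np.stack([
        stats.multivariate_normal.pdf(Y, params.means[k], params.covariances[k])
        for k in range(K)], axis=1)  # T x K
    total = 0.0
    gamma = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = params.initial[path[0]] * dens[0, path[0]]
        for t in range(1, T):
            p *= params.transitions[path[t - 1], path[t]] * dens[t, path[t]]
        total += p
        for t, k in enumerate(path):
            gamma[t, k] += p
    return np.log(total), gamma / total


class TestEnumerationOracle:
    @pytest.mark.parametrize("T,K,D,seed", [(6, 2, 2, 0), (5, 3, 2, 1),
                                            (8, 2, 1, 2), (4, 3, 3, 3)])
    def test_forward_loglik_and_posterior(self, T, K, D, seed):
        rng = np.random.default_rng(seed)
        params = _random_params(rng, K, D)
        Y = rng.normal(size=(T, D))
        ll_oracle, gamma_oracle = _enumerate_paths(params, Y)
        assert hmm_loglik(params, Y) == pytest.approx(ll_oracle, abs=1e-8)
        path = hmm_decode(params, Y)
        assert np.abs(path.gamma - gamma_oracle).max() < 1e-8

    def test_viterbi_matches_best_path(self):
        rng = np.random.default_rng(4)
        params = _random_params(rng, 2, 2)
        Y = rng.normal(size=(6, 2))
        dens = np.stack([
            stats.multivariate_normal.logpdf(Y, params.means[k],
                                             params.covariances[k])
            for k in range(2)], axis=1)
        best, best_lp = None, -np.inf
        for path in itertools.product(range(2), repeat=6):
            lp = np.log(params.initial[path[0]]) + dens[0, path[0]]
            for t in range(1, 6):
                lp += (np.log(params.transitions[path[t - 1], path[t]])
                       + dens[t, path[t]])
            if lp > best_lp:
                best, best_lp = path, lp
        assert tuple(hmm_decode(params, Y).viterbi) == best


class TestHmmlearnOracle:
    def test_loglik_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(5)
        params = _random_params(rng, 3, 2)
        Y = rng.normal(size=(40, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ref.startprob_ = params.initial
        ref.transmat_ = params.transitions
        ref.means_ = params.means
        ref.covars_ = params.covariances
        assert hmm_loglik(params, Y) == pytest.approx(ref.score(Y), abs=1e-8)

    def test_posterior_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(6)
        params = _random_params(rng, 2, 3)
        Y = rng.normal(size=(30, 3))
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                   init_params="")
        ref.startprob_ = params.initial
        ref.transmat_ = params.transitions
        ref.means_ = params.means
        ref.covars_ = params.covariances
        _, post = ref.score_samples(Y)
        assert np.abs(hmm_decode(params, Y).gamma - post).max() < 1e-8

    def test_multi_sequence_loglik(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(7)
        params = _random_params(rng, 2, 2)
        Y = rng.normal(size=(50, 2))
        lengths = [20, 30]
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                   init_params="")
        ref.startprob_ = params.initial
        ref.transmat_ = params.transitions
        ref.means_ = params.means
        ref.covars_ = params.covariances
        assert hmm_loglik(params, Y, lengths) == pytest.approx(
            ref.score(Y, lengths), abs=1e-8)


# ---------------------------------------------------------------------------
# standardize / PCA
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_three_point_column(self):
        out = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        X = rng.normal(size=(50, 4))
        once = standardize(X)
        assert np.allclose(standardize(once), once, atol=1e-12)

    def test_zero_mean(self, rng):
        out = standardize(rng.normal(size=(50, 4)))
        assert np.abs(out.mean(axis=0)).max() < 1e-10
        assert np.abs(out.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_column_named(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 2] = np.arange(10) ** 2
        with pytest.raises(ValueError, match=r"\[1\]"):
            standardize(X)


class TestPca:
    def test_rank_one(self, rng):
        u = rng.normal(size=30)
        v = rng.normal(size=5)
        proj = pca_fit(np.outer(u, v), var_threshold=0.999999)
        assert proj.n_components == 1
        assert proj.explained_ratio[0] == pytest.approx(1.0)

    def test_isotropic_dimension(self, rng):
        X = rng.normal(size=(10_000, 20))
        proj = pca_fit(X, var_threshold=0.9)
        assert abs(proj.n_components - 18) <= 1

    def test_round_trip_full_rank(self, rng):
        X = rng.normal(size=(100, 6))
        proj = pca_fit(X, var_threshold=1.0)
        assert np.abs(proj.inverse_transform(proj.transform(X)) - X).max() < 1e-8

    def test_threshold_boundary(self, rng):
        X = rng.normal(size=(500, 8)) * np.array([4, 3, 2, 1, 1, 1, 1, 1])
        proj = pca_fit(X, var_threshold=0.8)
        cum = np.cumsum(proj.explained_ratio)
        full = pca_fit(X, var_threshold=1.0)
        cum_full = np.cumsum(full.explained_ratio)
        D = proj.n_components
        assert cum_full[D - 1] >= 0.8
        assert D == 1 or cum_full[D - 2] < 0.8

    def test_bad_threshold(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(20, 3)), var_threshold=1.5)


# ---------------------------------------------------------------------------
# EM training and decoding
# ---------------------------------------------------------------------------

def _two_state_data(rng, T=2000, sep=6.0):
    means = np.array([[0.0, 0.0], [sep, 0.0]])
    path = np.empty(T, dtype=int)
    path[0] = 0
    for t in range(1, T):
        stay = rng.random() < 0.9
        path[t] = path[t - 1] if stay else 1 - path[t - 1]
    Y = means[path] + rng.normal(size=(T, 2))
    return Y, path


class TestEm:
    def test_two_state_recovery(self, rng):
        Y, path = _two_state_data(rng)
        model = hmm_fit(Y, 2, seed=0, n_restarts=2, max_iter=50)
        decoded = hmm_decode(model, Y).viterbi
        acc = max((decoded == path).mean(), (1 - decoded == path).mean())
        assert acc >= 0.95

    def test_k1_reduces_to_gaussian(self, rng):
        Y = rng.normal(size=(200, 3))
        model = hmm_fit(Y, 1, seed=0, n_restarts=1, max_iter=100, tol=1e-10)
        direct = stats.multivariate_normal.logpdf(
            Y, model.means[0], model.covariances[0]).sum()
        assert hmm_loglik(model, Y) == pytest.approx(direct, abs=1e-8)

    def test_loglik_nondecreasing(self, rng):
        Y, _ = _two_state_data(rng, T=500)
        model = hmm_fit(Y, 2, seed=1, n_restarts=1, max_iter=30)
        diffs = np.diff(model.loglik_trace)
        assert (diffs >= -1e-8 * abs(model.loglik_trace[0])).all()

    def test_transition_rows_stochastic(self, rng):
        Y, _ = _two_state_data(rng, T=400)
        model = hmm_fit(Y, 2, seed=2, n_restarts=1, max_iter=20)
        assert np.abs(model.transitions.sum(axis=1) - 1).max() < 1e-10
        for k in range(2):
            np.linalg.cholesky(model.covariances[k])

    def test_sequence_boundaries_respected(self, rng):
        # loglik of concatenated independent chains = sum of per-chain logliks
        params = _random_params(np.random.default_rng(8), 2, 2)
        A = rng.normal(size=(15, 2))
        B = rng.normal(size=(10, 2))
        joint = hmm_loglik(params, np.vstack([A, B]), lengths=[15, 10])
        assert joint == pytest.approx(
            hmm_loglik(params, A) + hmm_loglik(params, B), abs=1e-10)

    def test_bad_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            hmm_loglik(_random_params(np.random.default_rng(0), 2, 2),
                       rng.normal(size=(10, 2)), lengths=[4, 4])


class TestDecode:
    def test_noiseless_recovery(self, rng):
        params = _random_params(np.random.default_rng(9), 3, 2, spread=8.0)
        path = rng.integers(0, 3, size=50)
        Y = params.means[path]
        assert np.array_equal(hmm_decode(params, Y).viterbi, path)

    def test_gamma_rows_sum_to_one(self, rng):
        params = _random_params(np.random.default_rng(10), 3, 2)
        sp = hmm_decode(params, rng.normal(size=(40, 2)))
        assert np.abs(sp.gamma.sum(axis=1) - 1).max() < 1e-10

    def test_gamma_argmax_agrees_with_viterbi(self, rng):
        Y, _ = _two_state_data(rng, T=600)
        model = hmm_fit(Y, 2, seed=3, n_restarts=1, max_iter=30)
        sp = hmm_decode(model, Y)
        assert (sp.gamma.argmax(axis=1) == sp.viterbi).mean() >= 0.9

    def test_dimension_mismatch(self, rng):
        params = _random_params(np.random.default_rng(11), 2, 3)
        with pytest.raises(ValueError):
            hmm_decode(params, rng.normal(size=(10, 2)))


# ---------------------------------------------------------------------------
# Fractional occupancy
# ---------------------------------------------------------------------------

class TestFractionalOccupancy:
    def test_counting(self):
        fo = fractional_occupancy(np.array([0, 0, 1, 2, 1]), K=3)
        assert np.allclose(fo, [0.4, 0.4, 0.2])

    def test_single_tr_one_hot(self):
        fo = fractional_occupancy(np.array([0, 2, 1]), K=3, interval=(1, 2))
        assert np.array_equal(fo, [0.0, 0.0, 1.0])

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            fractional_occupancy(np.array([0, 1]), K=2, interval=(1, 1))

    def test_soft_mode_averages_gamma(self, rng):
        gamma = rng.random((10, 3))
        gamma /= gamma.sum(axis=1, keepdims=True)
        sp = StatePath(gamma=gamma, viterbi=gamma.argmax(axis=1))
        fo = fractional_occupancy(sp, K=3, interval=(2, 7), soft=True)
        assert np.allclose(fo, gamma[2:7].mean(axis=0))

    @given(st.lists(st.integers(0, 2), min_size=6, max_size=24))
    def test_disjoint_window_identity(self, labels):
        labels = np.asarray(labels[: 3 * (len(labels) // 3)])
        whole = fractional_occupancy(labels, K=3)
        parts = [fractional_occupancy(labels, K=3, interval=(i, i + 3))
                 for i in range(0, len(labels), 3)]
        assert np.allclose(np.mean(parts, axis=0), whole, atol=1e-12)

    def test_simplex(self, rng):
        labels = rng.integers(0, 4, 100)
        fo = fractional_occupancy(labels, K=4)
        assert fo.sum() == 1.0
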