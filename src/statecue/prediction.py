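"""Ridge prediction of windowed appetite from state fractional occupancies.

The estimator is ordinary ridge regression (closed form on centered data,
unpenalized intercept).  Validation follows a nested leave-one-subject-out
scheme: per outer fold, confound residualization (age, sex, head motion) and
0–1 scaling are fitted on training rows only, and the penalty λ is chosen on
an inner subject-level 5-fold split by a joint accuracy–stability criterion
(Euclidean distance to the ideal point (1, 1) after min-max scaling both
axes over the candidate grid).  Feature importance uses a subject-level
bootstrap of the refitted coefficients with BH-FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_CONFOUNDS = ("age", "sex", "motion")


def default_lambda_grid(n: int = 20) -> np.ndarray:
    """Candidate penalties: n values logarithmically spaced in [1e-3, 1e3]."""
    return np.logspace(-3.0, 3.0, n)


@dataclass
class RidgeModel:
    weights: np.ndarray
    intercept: float
    lam: float


@dataclass
class CVResult:
    per_subject_r: np.ndarray
    individual_mean_r: float
    individual_se: float
    group_r: float
    lambda_per_fold: np.ndarray
    group_lambda: float
    final_weights: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ImportanceResult:
    mean: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    B: int


# ---------------------------------------------------------------------------
# Preprocessing (train-fitted, applied to test)
# ---------------------------------------------------------------------------

def residualize_confounds(train_X: np.ndarray, train_C: np.ndarray,
                          test_X: np.ndarray | None = None,
                          test_C: np.ndarray | None = None):
    """Regress confounds out of each feature with training-fitted OLS.

    A rank-deficient confound matrix (e.g. a constant 'sex' column in a
    single-sex sample) has offending columns dropped with a warning.  Returns
    (train_residuals, test_adjusted, coefficients, kept_columns).
    """
    train_X = np.asarray(train_X, float)
    C = np.column_stack([np.ones(len(train_X)), np.asarray(train_C, float)])
    kept = _independent_columns(C)
    if len(kept) < C.shape[1]:
        dropped = sorted(set(range(C.shape[1])) - set(kept))
        log.warning("dropping rank-deficient confound column(s) %s",
                    [d - 1 for d in dropped])  # -1: skip the intercept
    C = C[:, kept]
    coef, *_ = np.linalg.lstsq(C, train_X, rcond=None)
    train_res = train_X - C @ coef
    test_res = None
    if test_X is not None:
        Ct = np.column_stack([np.ones(len(test_X)), np.asarray(test_C, float)])
        test_res = np.asarray(test_X, float) - Ct[:, kept] @ coef
    return train_res, test_res, coef, kept


def _independent_columns(C: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    kept: list[int] = []
    for j in range(C.shape[1]):
        cand = C[:, kept + [j]]
        if np.linalg.matrix_rank(cand, tol=tol) == len(kept) + 1:
            kept.append(j)
    return kept


def minmax_scale(train: np.ndarray, test: np.ndarray | None = None):
    """Scale features to the training 0–1 range; test rows may land outside
    [0, 1] (no clipping).  Zero-range features map to 0 with a warning."""
    train = np.asarray(train, float)
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    zero = span == 0
    if zero.any():
        log.warning("zero-range feature(s) %s mapped to 0",
                    np.nonzero(zero)[0].tolist())
    safe = np.where(zero, 1.0, span)
    train_s = np.where(zero, 0.0, (train - lo) / safe)
    test_s = None
    if test is not None:
        test = np.asarray(test, float)
        test_s = np.where(zero, 0.0, (test - lo) / safe)
    return train_s, test_s, (lo, hi)


class FoldPreprocessor:
    """Train-fitted residualization + min-max scaling, reusable on test rows."""

    def __init__(self, confound_coef, kept, minmax_params):
        self.confound_coef = confound_coef
        self.kept = kept
        self.minmax_params = minmax_params

    @classmethod
    def fit(cls, X: np.ndarray, C: np.ndarray):
        res, _, coef, kept = residualize_confounds(X, C)
        scaled, _, params = minmax_scale(res)
        return cls(coef, kept, params), scaled

    def transform(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        Ct = np.column_stack([np.ones(len(X)), np.asarray(C, float)])
        res = np.asarray(X, float) - Ct[:, self.kept] @ self.confound_coef
        lo, hi = self.minmax_params
        span = hi - lo
        zero = span == 0
        safe = np.where(zero, 1.0, span)
        return np.where(zero, 0.0, (res - lo) / safe)


# ---------------------------------------------------------------------------
# Ridge estimator
# ---------------------------------------------------------------------------

def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeModel:
    """Closed-form ridge on centered data with an unpenalized intercept:
    w = (XᵀX + λI)⁻¹ Xᵀy."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    try:
        w = linalg.solve(A, Xc.T @ yc, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular normal equations; use lambda > 0") from exc
    return RidgeModel(weights=w, intercept=float(ym - xm @ w), lam=float(lam))


def ridge_predict(model: RidgeModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, float) @ model.weights + model.intercept


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 when either side is constant (undefined), logged."""
    if np.std(a) == 0 or np.std(b) == 0:
        log.warning("constant series in correlation; returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Row assembly
# ---------------------------------------------------------------------------

def _subject_arrays(dataset, confounds):
    """Per-subject (X, y, C) triples from WindowedFeatures-like objects."""
    out = []
    for wf in dataset:
        X = np.asarray(wf.FO, float)
        y = np.asarray(wf.target, float)
        cov = []
        for name in confounds:
            v = wf.covariates.get(name, 0.0)
            if isinstance(v, str):  # categorical (e.g. sex) -> stable code
                v = float(abs(hash(v)) % 1000)
            cov.append(float(v))
        C = np.tile(cov, (len(y), 1)) if confounds else np.empty((len(y), 0))
        out.append((X, y, C))
    return out


def _stack(triples, idx):
    X = np.vstack([triples[i][0] for i in idx])
    y = np.concatenate([triples[i][1] for i in idx])
    C = np.vstack([triples[i][2] for i in idx])
    return X, y, C


# ---------------------------------------------------------------------------
# Inner-loop λ selection
# ---------------------------------------------------------------------------

def select_lambda(triples, grid: np.ndarray, inner_folds: int = 5,
                  seed: int = 0, n_repeats: int = 1):
    """Joint accuracy–stability λ selection on subject-level inner folds.

    Accuracy per λ is the mean held-out Pearson r over folds; stability is
    the mean pairwise correlation among the fold models' weight vectors.
    Both axes are min-max scaled over the grid and the λ minimizing the
    Euclidean distance to (1, 1) wins (ties break to the smaller λ).
    Returns (lambda, distances over the grid).
    """
    n = len(triples)
    if n < inner_folds:
        raise ValueError("need at least as many training subjects as inner folds")
    rng = np.random.default_rng(seed)
    G = len(grid)
    acc = np.zeros(G)
    stab = np.zeros(G)
    for _ in range(n_repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, inner_folds)
        fold_acc = np.zeros((G, inner_folds))
        fold_w = np.zeros((G, inner_folds, triples[0][0].shape[1]))
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            Xtr, ytr, Ctr = _stack(triples, train_idx)
            Xte, yte, Cte = _stack(triples, test_idx)
            prep, Xtr_s = FoldPreprocessor.fit(Xtr, Ctr)
            Xte_s = prep.transform(Xte, Cte)
            XtX = Xtr_s.T @ Xtr_s  # shared across the grid
            for g, lam in enumerate(grid):
                model = ridge_fit(Xtr_s, ytr, lam)
                pred = ridge_predict(model, Xte_s)
                fold_acc[g, f] = _safe_pearson(yte, pred)
                fold_w[g, f] = model.weights
        acc += fold_acc.mean(axis=1) / n_repeats
        for g in range(G):
            stab[g] += _mean_pairwise_corr(fold_w[g]) / n_repeats
    dist = _joint_distance(acc, stab)
    best = int(np.argmin(dist))  # argmin takes the first (smaller λ) on ties
    return float(grid[best]), dist


def _mean_pairwise_corr(W: np.ndarray) -> float:
    m = W.shape[0]
    vals = []
    for i in range(m):
        for j in range(i + 1, m):
            vals.append(_safe_pearson(W[i], W[j]))
    return float(np.mean(vals)) if vals else 0.0


def _joint_distance(acc: np.ndarray, stab: np.ndarray) -> np.ndarray:
    def scale(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.full_like(v, 0.5)
    a, s = scale(acc), scale(stab)
    return np.hypot(1.0 - a, 1.0 - s)


# ---------------------------------------------------------------------------
# Outer LOSO loop, cross-stimulus generalization, bootstrap importance
# ---------------------------------------------------------------------------

def loso_cv(dataset, grid: np.ndarray | None = None,
            confounds=DEFAULT_CONFOUNDS, seed: int = 0,
            inner_folds: int = 5, inner_repeats: int = 1) -> CVResult:
    """Nested leave-one-subject-out cross-validation.

    Per outer fold the held-out subject is predicted by a model refitted on
    all training rows with the inner-selected λ; the group λ minimizes the
    mean inner-criterion distance across folds, and the group-level r
    correlates the target with the dot product of the final model weights
    and the per-window mean (preprocessed) FO.
    """
    if len(dataset) < 3:
        raise ValueError("need at least three subjects")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, float)
    triples = _subject_arrays(dataset, confounds)
    n = len(triples)
    rng = np.random.default_rng(seed)
    per_r = np.empty(n)
    lam_per_fold = np.empty(n)
    dist_sum = np.zeros(len(grid))
    for s in range(n):
        train_idx = [i for i in range(n) if i != s]
        inner_seed = int(rng.integers(0, 2**31 - 1))
        lam, dist = select_lambda([triples[i] for i in train_idx], grid,
                                  inner_folds=inner_folds, seed=inner_seed,
                                  n_repeats=inner_repeats)
        dist_sum += dist
        Xtr, ytr, Ctr = _stack(triples, train_idx)
        Xte, yte, Cte = _stack(triples, [s])
        prep, Xtr_s = FoldPreprocessor.fit(Xtr, Ctr)
        model = ridge_fit(Xtr_s, ytr, lam)
        pred = ridge_predict(model, prep.transform(Xte, Cte))
        per_r[s] = _safe_pearson(yte, pred)
        lam_per_fold[s] = lam

    group_lambda = float(grid[int(np.argmin(dist_sum / n))])
    X_all, y_all, C_all = _stack(triples, list(range(n)))
    prep, X_all_s = FoldPreprocessor.fit(X_all, C_all)
    final = ridge_fit(X_all_s, y_all, group_lambda)
    group_r = _group_level_r(triples, X_all_s, final)
    return CVResult(per_subject_r=per_r,
                    individual_mean_r=float(per_r.mean()),
                    individual_se=float(per_r.std(ddof=1) / np.sqrt(n)),
                    group_r=group_r, lambda_per_fold=lam_per_fold,
                    group_lambda=group_lambda, final_weights=final.weights)


def _group_level_r(triples, X_scaled: np.ndarray, model: RidgeModel) -> float:
    """Correlate the target with mean-FO · weights (windows must align)."""
    W = len(triples[0][1])
    if any(len(t[1]) != W for t in triples):
        log.warning("window counts differ across subjects; group r skipped")
        return float("nan")
    X3 = X_scaled.reshape(len(triples), W, -1)
    group_pred = X3.mean(axis=0) @ model.weights
    return _safe_pearson(triples[0][1], group_pred)


def cross_generalize(train_dataset, test_dataset, group_lambda: float,
                     confounds=DEFAULT_CONFOUNDS) -> CVResult:
    """Train on all rows of one stimulus, evaluate on the other."""
    tr = _subject_arrays(train_dataset, confounds)
    te = _subject_arrays(test_dataset, confounds)
    if tr[0][0].shape[1] != te[0][0].shape[1]:
        raise ValueError("feature counts differ between datasets")
    Xtr, ytr, Ctr = _stack(tr, list(range(len(tr))))
    prep, Xtr_s = FoldPreprocessor.fit(Xtr, Ctr)
    model = ridge_fit(Xtr_s, ytr, group_lambda)
    per_r = np.array([
        _safe_pearson(y, ridge_predict(model, prep.transform(X, C)))
        for X, y, C in te])
    Xte_all = np.vstack([prep.transform(X, C) for X, _, C in te])
    group_r = _group_level_r(te, Xte_all, model)
    n = len(per_r)
    return CVResult(per_subject_r=per_r,
                    individual_mean_r=float(per_r.mean()),
                    individual_se=float(per_r.std(ddof=1) / np.sqrt(n)),
                    group_r=group_r, lambda_per_fold=np.full(n, group_lambda),
                    group_lambda=float(group_lambda),
                    final_weights=model.weights)


def bootstrap_importance(dataset, group_lambda: float, B: int = 5000,
                         seed: int = 0, confounds=DEFAULT_CONFOUNDS,
                         q: float = 0.05) -> ImportanceResult:
    """Subject-level bootstrap of the ridge coefficients.

    Subjects are resampled with replacement (a degenerate draw with a single
    distinct subject is redrawn, logged); preprocessing is refitted inside
    every resample.  Z = mean/SD of each coefficient across resamples,
    p = 2(1 − Φ(|Z|)), BH-FDR flags at ``q``.
    """
    if B < 2:
        raise ValueError("B must be >= 2 for a bootstrap SD")
    triples = _subject_arrays(dataset, confounds)
    n = len(triples)
    rng = np.random.default_rng(seed)
    coefs = np.empty((B, triples[0][0].shape[1]))
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= 2:
                break
            log.warning("degenerate bootstrap resample redrawn")
        X, y, C = _stack(triples, idx)
        prep, X_s = FoldPreprocessor.fit(X, C)
        coefs[b] = ridge_fit(X_s, y, group_lambda).weights
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, np.inf * np.sign(mean))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ImportanceResult(mean=mean, sd=sd, z=z, p=p,
                            significant=bh_fdr(p, q), B=B)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, alpha=q, method="fdr_bh")[0]
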