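"""Subject-level associations: state expression, group contrasts, partial
correlations, condition-wise occupancy comparisons, and BCa bootstrap
mediation.

State expression is the Pearson correlation between a subject's windowed
fractional-occupancy course for one state and the group appetite target,
concatenated across runs; it quantifies how tightly that state tracks the
group's appetite fluctuations.  Mediation follows the classic two-path OLS
decomposition (a: X→M, b: M→Y|X, c: total, c′: direct) with a
bias-corrected accelerated (BCa) bootstrap interval on the indirect effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import bh_fdr

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# State expression
# ---------------------------------------------------------------------------

def state_expression(fo_by_run: list[np.ndarray],
                     target_by_run: list[np.ndarray]) -> float:
    """Correlation between one state's windowed FO and the group appetite
    target, concatenated across runs.  NaN (missing) when the FO course is
    constant."""
    fo = np.concatenate([np.asarray(f, float) for f in fo_by_run])
    tg = np.concatenate([np.asarray(t, float) for t in target_by_run])
    if fo.shape != tg.shape:
        raise ValueError("window counts differ between FO and target")
    if fo.size < 10:
        raise ValueError("need at least 10 windows for state expression")
    if fo.std() == 0 or tg.std() == 0:
        log.warning("constant series; state expression undefined")
        return float("nan")
    return float(np.corrcoef(fo, tg)[0, 1])


# ---------------------------------------------------------------------------
# Group comparison and partial correlation
# ---------------------------------------------------------------------------

def group_compare(a: np.ndarray, b: np.ndarray, welch: bool = False
                  ) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance; Welch by option)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two members")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ coef


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None
                        ) -> tuple[float, float]:
    """Pearson correlation of OLS residuals of x and y on the covariates;
    p from the t distribution with n − q − 2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        q = 0
        rx, ry = x, y
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        q = C.shape[1]
        if n <= q + 2:
            raise ValueError("need n > #covariates + 2")
        D = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        rx = _residualize(x, D)
        ry = _residualize(y, D)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        log.warning("zero residual vector; partial correlation undefined")
        return float("nan"), float("nan")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - q - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# Condition-wise FO comparison (one-way repeated measures)
# ---------------------------------------------------------------------------

@dataclass
class RMAnovaResult:
    F: float
    p: float
    df: tuple[int, int]
    pairwise: pd.DataFrame
    n_subjects: int


def condition_fo_compare(values: np.ndarray, conditions: list[str] | None = None,
                         q: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA (subject as blocking factor) on an
    n_subjects x n_conditions table, with BH-corrected pairwise paired
    t-tests.  Subjects with any missing cell are dropped with a warning."""
    X = np.asarray(values, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("expect an n_subjects x n_conditions matrix")
    complete = ~np.isnan(X).any(axis=1)
    if not complete.all():
        log.warning("dropping %d subject(s) with missing cells",
                    int((~complete).sum()))
    X = X[complete]
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least two complete subjects")
    names = conditions if conditions is not None else [f"c{j}" for j in range(k)]

    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_cond <= 1e-12 * max(ss_tot, 1.0):
        F, p = 0.0, 1.0
    else:
        F = (ss_cond / df1) / (ss_err / df2) if ss_err > 0 else np.inf
        p = float(stats.f.sf(F, df1, df2))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            t, pp = stats.ttest_rel(X[:, i], X[:, j])
            rows.append({"a": names[i], "b": names[j],
                         "t": float(t), "p": float(pp)})
    pw = pd.DataFrame(rows)
    if len(pw):
        pw["significant"] = bh_fdr(pw["p"].to_numpy(), q)
    return RMAnovaResult(F=float(F), p=float(p), df=(df1, df2), pairwise=pw,
                         n_subjects=n)


# ---------------------------------------------------------------------------
# BCa mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    cprime_ci: tuple[float, float]
    B: int
    prop_mediated: float
    significant: bool
    full_mediation: bool
    degenerate: bool = False


def _design(cols: list[np.ndarray]) -> np.ndarray:
    return np.column_stack([np.ones(len(cols[0]))] + cols)


def _paths(X, M, Y, C):
    """OLS path coefficients (a, b, c, c_prime) with shared covariates."""
    cov_cols = [C[:, j] for j in range(C.shape[1])]
    a = np.linalg.lstsq(_design([X] + cov_cols), M, rcond=None)[0][1]
    bc = np.linalg.lstsq(_design([X, M] + cov_cols), Y, rcond=None)[0]
    c = np.linalg.lstsq(_design([X] + cov_cols), Y, rcond=None)[0][1]
    return float(a), float(bc[2]), float(c), float(bc[1])


def _batched_paths(X, M, Y, C, idx):
    """Vectorized (a·b, c') over bootstrap index matrix ``idx`` (B x n)."""
    def solve(design, target):
        G = np.einsum("bni,bnj->bij", design, design)
        h = np.einsum("bni,bn->bi", design, target)
        G += 1e-12 * np.eye(design.shape[2])
        return np.linalg.solve(G, h[..., None])[..., 0]

    ones = np.ones(idx.shape)
    Cb = C[idx]  # B x n x q
    d1 = np.concatenate([ones[..., None], X[idx][..., None], Cb], axis=2)
    a = solve(d1, M[idx])[:, 1]
    d2 = np.concatenate([ones[..., None], X[idx][..., None],
                         M[idx][..., None], Cb], axis=2)
    coefs2 = solve(d2, Y[idx])
    b = coefs2[:, 2]
    cprime = coefs2[:, 1]
    return a * b, cprime


def mediation_bca(X: np.ndarray, M: np.ndarray, Y: np.ndarray,
                  covariates: np.ndarray | None = None, B: int = 10000,
                  seed: int = 0, alpha: float = 0.05) -> MediationResult:
    """Two-path mediation with BCa bootstrap inference on a·b.

    Subjects are resampled with replacement; the bias term z0 comes from the
    proportion of bootstrap replicates below the point estimate, and the
    acceleration from the jackknife skewness of the indirect effect.  Full
    mediation is reported when the indirect CI excludes 0 while the c'
    (percentile) CI includes 0.
    """
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    Y = np.asarray(Y, float)
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    if np.isnan(np.concatenate([X, M, Y, C.ravel()])).any():
        raise ValueError("complete cases required (NaN present)")

    a, b, c, c_prime = _paths(X, M, Y, C)
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot_ind, boot_cp = _batched_paths(X, M, Y, C, idx)

    if boot_ind.std() == 0:
        log.warning("zero bootstrap variance; degenerate interval")
        ci = (indirect, indirect)
        cp_ci = (c_prime, c_prime)
        return MediationResult(a=a, b=b, c=c, c_prime=c_prime,
                               indirect=indirect, ci_low=ci[0], ci_high=ci[1],
                               cprime_ci=cp_ci, B=B,
                               prop_mediated=_prop_mediated(c, c_prime),
                               significant=False, full_mediation=False,
                               degenerate=True)

    # jackknife acceleration
    jack = np.empty(n)
    keep = np.arange(n)
    for i in range(n):
        sel = keep != i
        ai, bi, _, _ = _paths(X[sel], M[sel], Y[sel], C[sel])
        jack[i] = ai * bi
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    accel = num / den if den > 0 else 0.0

    ci = _bca_interval(boot_ind, indirect, accel, alpha)
    cp_lo, cp_hi = np.quantile(boot_cp, [alpha / 2, 1 - alpha / 2])
    significant = not (ci[0] <= 0.0 <= ci[1])
    full = significant and (cp_lo <= 0.0 <= cp_hi)
    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
                           ci_low=float(ci[0]), ci_high=float(ci[1]),
                           cprime_ci=(float(cp_lo), float(cp_hi)), B=B,
                           prop_mediated=_prop_mediated(c, c_prime),
                           significant=significant, full_mediation=full)


def _prop_mediated(c: float, c_prime: float) -> float:
    return (c - c_prime) / c if c != 0 else float("nan")


def _bca_interval(boot: np.ndarray, point: float, accel: float,
                  alpha: float) -> tuple[float, float]:
    B = len(boot)
    frac = np.clip((boot < point).mean(), 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(frac)
    out = []
    for z in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        out.append(np.quantile(boot, np.clip(stats.norm.cdf(adj), 0.0, 1.0)))
    return float(out[0]), float(out[1])
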