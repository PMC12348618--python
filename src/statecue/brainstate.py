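"""State characterization and model-order selection.

Activation maps summarize the mean standardized parcel signal during the TRs
a state occupies; per-state functional connectivity (FC) is the Pearson
matrix over those TRs, contrasted against the mean FC of the other states
with one-sample t-tests across subjects (BH-FDR corrected).  The number of
states K is selected by split-half stability: subjects are split in half,
independent models are fitted on each half, both decode a common target set,
and agreement is scored by zRand, NMI, and the activity concordance index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hmm import hmm_decode, hmm_fit, pca_fit, standardize
from .metrics import match_states, nmi, zrand
from .prediction import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class StateProfile:
    state: int
    activation_map: np.ndarray          # P-vector (mean standardized signal)
    fc: np.ndarray | None               # P x P mean Pearson FC across subjects
    fc_network: np.ndarray | None       # network-block reduction (if lookup given)
    contrast_t: np.ndarray | None       # P x P t-values (state vs other states)
    contrast_sig: np.ndarray | None     # P x P BH-FDR significance mask
    n_trs_used: int
    empty: bool = False


@dataclass
class StabilityReport:
    k_range: list[int]
    zrand_mean: dict[int, float]
    zrand_sd: dict[int, float]
    nmi_mean: dict[int, float]
    nmi_sd: dict[int, float]
    concordance_mean: dict[int, float]
    concordance_sd: dict[int, float]
    n_repeats: dict[int, int]
    chosen_k: int = 0
    composite: dict[int, float] = field(default_factory=dict)


def activation_maps(X_std: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """K x P mean standardized parcel vectors over the TRs of each state."""
    maps = np.zeros((K, X_std.shape[1]))
    for k in range(K):
        sel = labels == k
        if sel.any():
            maps[k] = X_std[sel].mean(axis=0)
    return maps


def state_profiles(series: list[np.ndarray], labels: list[np.ndarray], K: int,
                   networks: np.ndarray | None = None, min_trs: int = 10,
                   q: float = 0.05) -> list[StateProfile]:
    """Per-state activation maps and FC contrasts.

    ``series`` holds each subject's standardized T x P matrix and ``labels``
    the matching hard state assignments.  Activation maps pool assigned TRs
    across subjects.  A subject contributes a state's FC only when the state
    occupies at least ``min_trs`` of their TRs.
    """
    if len(series) != len(labels):
        raise ValueError("series and labels must pair one-to-one")
    P = series[0].shape[1]

    # pooled activation maps and per-subject FC matrices
    pooled_sum = np.zeros((K, P))
    pooled_n = np.zeros(K, dtype=int)
    subj_fc: list[dict[int, np.ndarray]] = []
    for X, lab in zip(series, labels):
        if X.shape[0] != len(lab):
            raise ValueError("series and labels lengths differ for a subject")
        fcs: dict[int, np.ndarray] = {}
        for k in range(K):
            sel = lab == k
            n_k = int(sel.sum())
            if n_k:
                pooled_sum[k] += X[sel].sum(axis=0)
                pooled_n[k] += n_k
            if n_k >= min_trs:
                with np.errstate(invalid="ignore"):
                    fc = np.corrcoef(X[sel].T)
                np.fill_diagonal(fc, 1.0)
                fcs[k] = np.nan_to_num(fc)
        subj_fc.append(fcs)

    profiles = []
    iu = np.triu_indices(P, k=1)
    for k in range(K):
        if pooled_n[k] == 0:
            log.warning("state %d has no assigned TRs; profile flagged empty", k)
            profiles.append(StateProfile(state=k, activation_map=np.zeros(P),
                                         fc=None, fc_network=None,
                                         contrast_t=None, contrast_sig=None,
                                         n_trs_used=0, empty=True))
            continue
        amap = pooled_sum[k] / pooled_n[k]

        diffs = []
        fcs_k = []
        for fcs in subj_fc:
            if k not in fcs:
                continue
            others = [fc for kk, fc in fcs.items() if kk != k]
            fcs_k.append(fcs[k])
            if others:
                diffs.append(fcs[k] - np.mean(others, axis=0))
        fc_mean = np.mean(fcs_k, axis=0) if fcs_k else None
        t_mat = sig_mat = None
        if len(diffs) >= 2:
            d = np.stack([dd[iu] for dd in diffs])  # subjects x connections
            t, p = stats.ttest_1samp(d, 0.0, axis=0)
            flags = bh_fdr(np.nan_to_num(p, nan=1.0), q)
            t_mat = np.zeros((P, P))
            sig_mat = np.zeros((P, P), dtype=bool)
            t_mat[iu] = np.nan_to_num(t)
            t_mat += t_mat.T
            sig_mat[iu] = flags
            sig_mat |= sig_mat.T
        profiles.append(StateProfile(
            state=k, activation_map=amap, fc=fc_mean,
            fc_network=_network_reduce(fc_mean, networks),
            contrast_t=t_mat, contrast_sig=sig_mat,
            n_trs_used=int(pooled_n[k])))
    return profiles


def _network_reduce(fc: np.ndarray | None,
                    networks: np.ndarray | None) -> np.ndarray | None:
    """Average a P x P matrix into network-by-network blocks."""
    if fc is None or networks is None:
        return None
    nets = np.unique(networks)
    out = np.empty((nets.size, nets.size))
    for i, a in enumerate(nets):
        for j, b in enumerate(nets):
            out[i, j] = fc[np.ix_(networks == a, networks == b)].mean()
    return out


def k_selection(series_by_subject: list[np.ndarray],
                k_range: range | list[int] = range(5, 13),
                n_repeats: int = 10, seed: int = 0,
                var_threshold: float | None = 0.9,
                n_components: int | None = None,
                n_restarts: int = 5, max_iter: int = 100,
                tol: float = 1e-5) -> StabilityReport:
    """Split-half stability over candidate state counts.

    Per repeat, subjects are randomly halved; an HMM is fitted independently
    on each half (after subject-wise standardization and a PCA projection
    shared across halves); both models decode the first half's data, and the
    two hard labelings are compared with zRand and NMI while the matched
    activation maps give the concordance index.  The chosen K maximizes the
    mean of the min-max-scaled metric means (override downstream if needed).
    """
    n_sub = len(series_by_subject)
    if n_sub < 4:
        raise ValueError("need at least four subjects for split-half stability")
    k_range = list(k_range)
    std_series = [standardize(X) for X in series_by_subject]
    proj = pca_fit(np.vstack(std_series), var_threshold=var_threshold,
                   n_components=n_components)
    reduced = [proj.transform(X) for X in std_series]

    rng = np.random.default_rng(seed)
    results: dict[int, dict[str, list[float]]] = {
        k: {"zrand": [], "nmi": [], "ci": []} for k in k_range}
    for rep in range(n_repeats):
        order = rng.permutation(n_sub)
        half_a = sorted(order[: n_sub // 2])
        half_b = sorted(order[n_sub // 2:])
        ya = np.vstack([reduced[i] for i in half_a])
        la = [len(reduced[i]) for i in half_a]
        yb = np.vstack([reduced[i] for i in half_b])
        lb = [len(reduced[i]) for i in half_b]
        target = ya
        target_lengths = la
        target_std = np.vstack([std_series[i] for i in half_a])
        for k in k_range:
            try:
                fit_seed = int(rng.integers(0, 2**31 - 1))
                ma = hmm_fit(ya, k, lengths=la, seed=fit_seed,
                             n_restarts=n_restarts, max_iter=max_iter, tol=tol)
                mb = hmm_fit(yb, k, lengths=lb, seed=fit_seed + 1,
                             n_restarts=n_restarts, max_iter=max_iter, tol=tol)
                pa = hmm_decode(ma, target, lengths=target_lengths).viterbi
                pb = hmm_decode(mb, target, lengths=target_lengths).viterbi
                maps_a = activation_maps(target_std, pa, k)
                maps_b = activation_maps(target_std, pb, k)
                _, ci = match_states(maps_a, maps_b)
                results[k]["zrand"].append(zrand(pa, pb))
                results[k]["nmi"].append(nmi(pa, pb))
                results[k]["ci"].append(ci)
            except Exception as exc:  # dropped repeat, logged
                log.warning("repeat %d failed for K=%d: %s", rep, k, exc)

    for k in k_range:
        if len(results[k]["zrand"]) < 3:
            raise RuntimeError(f"fewer than 3 surviving repeats for K={k}")

    def _stats(key):
        means = {k: float(np.nanmean(results[k][key])) for k in k_range}
        sds = {k: float(np.nanstd(results[k][key])) for k in k_range}
        return means, sds

    zm, zs = _stats("zrand")
    nm, ns = _stats("nmi")
    cm, cs = _stats("ci")
    report = StabilityReport(
        k_range=k_range, zrand_mean=zm, zrand_sd=zs, nmi_mean=nm, nmi_sd=ns,
        concordance_mean=cm, concordance_sd=cs,
        n_repeats={k: len(results[k]["zrand"]) for k in k_range})

    composite = np.zeros(len(k_range))
    for means in (zm, nm, cm):
        vals = np.array([means[k] for k in k_range], dtype=float)
        span = vals.max() - vals.min()
        scaled = (vals - vals.min()) / span if span > 0 else np.full_like(vals, 0.5)
        composite += scaled / 3.0
    report.composite = {k: float(c) for k, c in zip(k_range, composite)}
    report.chosen_k = int(k_range[int(np.argmax(composite))])
    return report
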