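"""Synthetic cohort generator.

Emulates the three inputs of the appetite brain-state analysis with known
latent structure: per-subject parcellated BOLD-like time series driven by a
shared hidden-state sequence, continuous rater event streams coupled to the
state sequence, and a subject covariate table with planted mediation paths
(BMI -> latent state-coupling gain -> craving) and two BMI-trajectory types.

All ground truth (state paths, emission model, coupling gains, trajectory
types) is stored on the cohort object so downstream recovery tests can
measure estimation error against the generative truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import (
    DOMAIN_COVARIATES,
    DOMAIN_GROUP,
    DOMAIN_MODEL,
    DOMAIN_RATER,
    DOMAIN_SUBJECT,
    moving_average,
    substream,
)

N_NETWORKS = 17
WINDOW_MIN = 5  # shortest usable run, in TRs (one sliding window)

# Monthly BMI-offset templates (kg/m^2): type 1 ramps up ~0.15/month; type 2 is
# flat for four months then declines 0.1/month.
DEFAULT_TRAJ_TYPES = (
    (0.0, 0.15, 0.30, 0.45, 0.60, 0.75),
    (0.0, 0.0, 0.0, 0.0, -0.10, -0.20),
)


def default_appetite_weights(k: int) -> np.ndarray:
    """Per-state appetite loadings: two appetitive states, two suppressive."""
    w = np.zeros(k)
    w[0] = w[1 % k] = 1.0
    if k >= 4:
        w[2] = w[3] = -1.0
    else:
        w[-1] = -1.0
    return w


@dataclass(frozen=True)
class SynthConfig:
    """Generative settings for one synthetic cohort.

    Defaults encode the reference study conditions used throughout the test
    suite: 20 subjects, one 500-TR run, 100 parcels in 17 network blocks,
    6 latent states with self-transition 0.9, parcel-level SNR 1, and planted
    mediation paths a = b = 0.5, c' = 0 with a gain–BMI correlation of 0.32.
    """

    n_subjects: int = 20
    n_raters: int = 12
    T_per_run: tuple[int, ...] = (500,)
    P: int = 100
    K_true: int = 6
    self_trans: float = 0.9
    jitter_eps: float = 0.1
    emission_sigma: float = 1.0
    appetite_weights: tuple[float, ...] | None = None
    appetite_noise: float = 0.1
    coupling_bmi_r: float = 0.32
    med_a: float = 0.5
    med_b: float = 0.5
    med_cprime: float = 0.0
    traj_types: tuple[tuple[float, ...], tuple[float, ...]] = DEFAULT_TRAJ_TYPES
    traj_noise_sd: float = 0.05
    traj_logit_slope: float = 1.2
    tr: float = 1.0
    seed: int = 0

    def weights(self) -> np.ndarray:
        if self.appetite_weights is None:
            return default_appetite_weights(self.K_true)
        w = np.asarray(self.appetite_weights, dtype=float)
        if w.shape != (self.K_true,):
            raise ValueError("appetite_weights must have length K_true")
        return w

    def validate(self) -> None:
        if self.K_true < 2:
            raise ValueError("invalid config: K_true must be >= 2")
        if self.P < self.K_true:
            raise ValueError("invalid config: P must be >= K_true")
        for p_name in ("self_trans", "jitter_eps"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"invalid config: {p_name} must lie in [0, 1]")
        if any(t < WINDOW_MIN for t in self.T_per_run):
            raise ValueError(f"invalid config: each run must have >= {WINDOW_MIN} TRs")
        if self.n_subjects < 1 or self.n_raters < 1:
            raise ValueError("invalid config: need at least one subject and rater")
        if self.med_a != 0.0 and not 0.0 < self.coupling_bmi_r < 1.0:
            raise ValueError("invalid config: coupling_bmi_r must lie in (0, 1) when med_a != 0")
        self.weights()


@dataclass
class TrueHMM:
    """Ground-truth emission/transition model behind a synthetic cohort."""

    means: np.ndarray          # K x P state mean activation vectors
    transitions: np.ndarray    # K x K row-stochastic
    initial: np.ndarray        # K
    active_networks: list[tuple[int, ...]]
    parcel_networks: np.ndarray  # P-vector of network ids (0..16)


@dataclass
class SynthCohort:
    """Generated cohort plus all generative ground truth."""

    config: SynthConfig
    true_model: TrueHMM
    group_path: list[np.ndarray]                      # per run, T-vector of states
    subject_paths: dict[int, list[np.ndarray]]        # subject -> per-run paths
    parcel_series: dict[tuple[int, int], np.ndarray]  # (subject, run) -> T x P
    appetite_truth: list[np.ndarray]                  # per run, T-vector in [0, 3]
    rater_events: dict[int, list[pd.DataFrame]]       # rater -> per-run events
    covariates: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.group_path)


def parcel_network_labels(P: int) -> np.ndarray:
    """Assign P parcels to 17 contiguous network blocks of near-equal size."""
    edges = np.linspace(0, P, N_NETWORKS + 1).astype(int)
    labels = np.empty(P, dtype=int)
    for net in range(N_NETWORKS):
        labels[edges[net]:edges[net + 1]] = net
    return labels


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def gen_true_model(cfg: SynthConfig, max_tries: int = 2000) -> TrueHMM:
    """Draw a block-structured state model.

    Each state elevates 1–3 of the 17 network blocks (mean +1 on their
    parcels, 0 elsewhere); states are redrawn until all pairwise cosine
    similarities between mean vectors are <= 0.5.  Transitions have diagonal
    ``self_trans`` with the remainder spread uniformly off-diagonal.
    """
    cfg.validate()
    rng = substream(cfg.seed, DOMAIN_MODEL)
    networks = parcel_network_labels(cfg.P)
    K = cfg.K_true

    means = np.zeros((K, cfg.P))
    active: list[tuple[int, ...]] = []
    for k in range(K):
        for _ in range(max_tries):
            n_blocks = int(rng.integers(1, 4))
            blocks = tuple(sorted(rng.choice(N_NETWORKS, size=n_blocks, replace=False)))
            vec = np.where(np.isin(networks, blocks), 1.0, 0.0)
            if all(_cosine(vec, means[j]) <= 0.5 for j in range(k)):
                break
        else:
            raise RuntimeError("could not draw sufficiently distinct state maps")
        means[k] = vec
        active.append(blocks)

    off = (1.0 - cfg.self_trans) / (K - 1)
    transitions = np.full((K, K), off)
    np.fill_diagonal(transitions, cfg.self_trans)
    initial = np.full(K, 1.0 / K)
    return TrueHMM(means=means, transitions=transitions, initial=initial,
                   active_networks=active, parcel_networks=networks)


def _sample_chain(rng: np.random.Generator, model: TrueHMM, T: int) -> np.ndarray:
    K = len(model.initial)
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(K, p=model.initial)
    for t in range(1, T):
        path[t] = rng.choice(K, p=model.transitions[path[t - 1]])
    return path


def _appetite_from_path(path: np.ndarray, w: np.ndarray) -> np.ndarray:
    raw = moving_average(w[path], WINDOW_MIN)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 1.5)
    return 3.0 * (raw - lo) / (hi - lo)


def _rating_cutpoints(appetite_runs: list[np.ndarray]) -> np.ndarray:
    """Fixed ordinal cut points at the 50/70/85th percentiles of the noiseless
    appetite course, guaranteeing all three levels occur."""
    pooled = np.concatenate(appetite_runs)
    return np.percentile(pooled, [50, 70, 85])


def _rater_events(rng: np.random.Generator, appetite: np.ndarray,
                  cuts: np.ndarray, noise_sd: float, tr: float) -> pd.DataFrame:
    noisy = appetite + rng.normal(0.0, noise_sd, size=appetite.shape)
    levels = np.digitize(noisy, cuts)  # 0 = no press, 1..3 ordinal appetite
    pressed = np.nonzero(levels > 0)[0]
    return pd.DataFrame({
        "onset": pressed * tr + 0.25 * tr,
        "duration": np.zeros(len(pressed)),
        "value": levels[pressed].astype(int),
    })


def gen_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a full cohort under ``cfg`` (deterministic given ``cfg.seed``)."""
    cfg.validate()
    model = gen_true_model(cfg)
    w = cfg.weights()
    K = cfg.K_true

    rng_group = substream(cfg.seed, DOMAIN_GROUP)
    group_path = [_sample_chain(rng_group, model, T) for T in cfg.T_per_run]
    appetite_truth = [_appetite_from_path(p, w) for p in group_path]
    cuts = _rating_cutpoints(appetite_truth)

    subject_paths: dict[int, list[np.ndarray]] = {}
    parcel_series: dict[tuple[int, int], np.ndarray] = {}
    for s in range(cfg.n_subjects):
        rng_s = substream(cfg.seed, DOMAIN_SUBJECT, s)
        paths = []
        for r, gp in enumerate(group_path):
            path = gp.copy()
            flip = rng_s.random(len(path)) < cfg.jitter_eps
            path[flip] = rng_s.integers(0, K, size=int(flip.sum()))
            paths.append(path)
            obs = model.means[path] + rng_s.normal(
                0.0, cfg.emission_sigma, size=(len(path), cfg.P))
            parcel_series[(s, r)] = obs
        subject_paths[s] = paths

    rater_events: dict[int, list[pd.DataFrame]] = {}
    for j in range(cfg.n_raters):
        rng_j = substream(cfg.seed, DOMAIN_RATER, j)
        rater_events[j] = [
            _rater_events(rng_j, app, cuts, cfg.appetite_noise, cfg.tr)
            for app in appetite_truth
        ]

    covariates = _gen_covariates(cfg)

    return SynthCohort(config=cfg, true_model=model, group_path=group_path,
                       subject_paths=subject_paths, parcel_series=parcel_series,
                       appetite_truth=appetite_truth, rater_events=rater_events,
                       covariates=covariates)


def _gen_covariates(cfg: SynthConfig) -> pd.DataFrame:
    """Subject covariates with planted mediation and trajectory structure.

    coupling_gain = med_a * BMI_std + noise  (noise SD set so that
    corr(gain, BMI) targets coupling_bmi_r); craving = med_b * gain +
    med_cprime * BMI_std + noise; trajectory type 1 probability is logistic
    in the standardized gain.
    """
    rng = substream(cfg.seed, DOMAIN_COVARIATES)
    n = cfg.n_subjects
    bmi = rng.normal(23.6, 3.5, size=n)
    age = rng.normal(20.8, 1.5, size=n)
    motion = np.abs(rng.normal(0.12, 0.04, size=n))
    bmi_std = (bmi - bmi.mean()) / bmi.std() if n > 1 else np.zeros(n)

    if cfg.med_a != 0.0:
        sigma_g = abs(cfg.med_a) * np.sqrt(1.0 / cfg.coupling_bmi_r**2 - 1.0)
    else:
        sigma_g = 1.0
    gain = cfg.med_a * bmi_std + rng.normal(0.0, sigma_g, size=n)
    craving = cfg.med_b * gain + cfg.med_cprime * bmi_std + rng.normal(0.0, 1.0, size=n)

    gain_sd = gain.std() if n > 1 and gain.std() > 0 else 1.0
    gain_std = (gain - gain.mean()) / gain_sd
    p_type1 = 1.0 / (1.0 + np.exp(-cfg.traj_logit_slope * gain_std))
    traj_type = np.where(rng.random(n) < p_type1, 1, 2)

    templates = np.asarray(cfg.traj_types, dtype=float)
    bmi_months = (bmi[:, None] + templates[traj_type - 1]
                  + rng.normal(0.0, cfg.traj_noise_sd, size=(n, 6)))

    cov = pd.DataFrame({
        "subject_id": [f"sub-{s:02d}" for s in range(n)],
        "bmi": bmi,
        "age": age,
        "sex": ["F"] * n,
        "motion": motion,
        "craving_post": craving,
        "coupling_gain": gain,
        "traj_type": traj_type,
    })
    for m in range(6):
        cov[f"bmi_m{m + 1}"] = bmi_months[:, m]
    return cov


# ---------------------------------------------------------------------------
# On-disk layout (TSV + JSON ground truth)
# ---------------------------------------------------------------------------

def write_cohort(cohort: SynthCohort, outdir: str | Path) -> Path:
    """Write the cohort as plain-text artifacts.

    Layout: ``sub-XX_run-YY_parcels.tsv`` (T x P, parcel-label header),
    ``rater-XX_run-YY_events.tsv`` (BIDS-style onset/duration/value),
    ``covariates.tsv``, ``parcel_networks.tsv`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parcel_labels = [f"parcel_{i:03d}" for i in range(cohort.config.P)]

    for (s, r), X in cohort.parcel_series.items():
        pd.DataFrame(X, columns=parcel_labels).to_csv(
            outdir / f"sub-{s:02d}_run-{r:02d}_parcels.tsv", sep="\t", index=False)
    for j, runs in cohort.rater_events.items():
        for r, ev in enumerate(runs):
            ev.to_csv(outdir / f"rater-{j:02d}_run-{r:02d}_events.tsv",
                      sep="\t", index=False)
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    pd.DataFrame({
        "parcel_id": parcel_labels,
        "network_17": cohort.true_model.parcel_networks,
    }).to_csv(outdir / "parcel_networks.tsv", sep="\t", index=False)

    truth = {
        "config": _config_dict(cohort.config),
        "group_path": [p.tolist() for p in cohort.group_path],
        "subject_paths": {str(s): [p.tolist() for p in paths]
                          for s, paths in cohort.subject_paths.items()},
        "state_means": cohort.true_model.means.tolist(),
        "transitions": cohort.true_model.transitions.tolist(),
        "appetite_truth": [a.tolist() for a in cohort.appetite_truth],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
    return outdir


def _config_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d["appetite_weights"] is not None:
        d["appetite_weights"] = list(d["appetite_weights"])
    d["T_per_run"] = list(d["T_per_run"])
    d["traj_types"] = [list(t) for t in d["traj_types"]]
    return d
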