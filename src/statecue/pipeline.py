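"""Config-driven orchestration of the full analysis.

Stages run in order (ratings -> brainstate -> alignment -> prediction ->
association -> trajectories), each reading the previous stage's plain-text
artifacts from the output directory, so any stage can be rerun standalone.
A manifest records the config hash, seeds, package version, artifact
checksums and timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import make_windows, windowed_features, WindowedFeatures
from .association import (condition_fo_compare, mediation_bca,
                          partial_correlation, state_expression)
from .brainstate import k_selection, state_profiles
from .hmm import (HMMParams, StatePath, hmm_decode, hmm_fit, pca_fit,
                  standardize)
from .prediction import (bootstrap_importance, cross_generalize,
                         default_lambda_grid, loso_cv)
from .ratings import group_average, resample_events, split_half_reliability
from .trajectories import cluster_trajectories, compare_types

log = logging.getLogger(__name__)

STAGE_ORDER = ["ratings", "hmm", "profiles", "align", "predict",
               "importance", "express", "mediate", "trajectories"]


@dataclass
class RunConfig:
    """All fixed analysis settings, serialized into every output bundle."""

    data_dir: str = "."
    out_dir: str = "out"
    tr: float = 1.0
    window_length: int = 5
    window_step: int = 2
    k: int | None = None
    k_range: tuple[int, int] = (5, 12)
    k_repeats: int = 10
    pca_var_threshold: float | None = 0.9
    pca_components: int | None = None
    hmm_restarts: int = 5
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-5
    lambda_grid_size: int = 20
    n_boot_importance: int = 5000
    n_boot_mediation: int = 10000
    n_iter_reliability: int = 5000
    fdr_q: float = 0.05
    expression_state: int | None = None
    conditions_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("window_length", "window_step", "k_repeats",
                     "lambda_grid_size", "n_boot_importance",
                     "n_boot_mediation", "n_iter_reliability",
                     "hmm_restarts", "hmm_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Input discovery
# ---------------------------------------------------------------------------

_PARCEL_RE = re.compile(r"sub-(\w+)_run-(\w+)_parcels\.tsv$")
_EVENT_RE = re.compile(r"rater-(\w+)_run-(\w+)_events\.tsv$")


def discover_inputs(data_dir: str | Path) -> dict:
    """Index parcel series, rater events and the covariate table on disk."""
    data_dir = Path(data_dir)
    parcels: dict[tuple[str, str], Path] = {}
    events: dict[tuple[str, str], Path] = {}
    for p in sorted(data_dir.iterdir()):
        m = _PARCEL_RE.search(p.name)
        if m:
            parcels[(m.group(1), m.group(2))] = p
        m = _EVENT_RE.search(p.name)
        if m:
            events[(m.group(1), m.group(2))] = p
    cov = data_dir / "covariates.tsv"
    if not parcels:
        raise FileNotFoundError(f"no parcel series found under {data_dir}")
    subjects = sorted({s for s, _ in parcels})
    runs = sorted({r for _, r in parcels})
    return {"parcels": parcels, "events": events,
            "covariates": cov if cov.exists() else None,
            "subjects": subjects, "runs": runs}


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run stage '{producer}' first")
    return path


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_ratings(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for run in inputs["runs"]:
        # TR count from any subject's parcel series of this run
        sub0 = inputs["subjects"][0]
        T = len(pd.read_csv(inputs["parcels"][(sub0, run)], sep="\t"))
        traces = []
        for (rater, r), path in sorted(inputs["events"].items()):
            if r != run:
                continue
            ev = pd.read_csv(path, sep="\t")
            traces.append(resample_events(ev, cfg.tr, T, rater_id=rater))
        if len(traces) < 2:
            raise ValueError(f"run {run}: need at least two raters")
        series = group_average(traces)
        df = pd.DataFrame({"appetite_z": series.values,
                           "appetite_hrf": series.hrf_convolved})
        p = out / f"run-{run}_appetite.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        rel = split_half_reliability(traces, n_iter=cfg.n_iter_reliability,
                                     seed=cfg.seed)
        rp = out / f"run-{run}_reliability.json"
        _write_json(rp, {"mean_corrected_r": rel.mean_corrected_r,
                         "p_value": rel.p_value, "n_iter": rel.n_iter})
        written.append(rp)
    return written


def _load_series(cfg: RunConfig):
    inputs = discover_inputs(cfg.data_dir)
    series: dict[tuple[str, str], np.ndarray] = {}
    for key, path in inputs["parcels"].items():
        series[key] = pd.read_csv(path, sep="\t").to_numpy(float)
    return inputs, series


def stage_hmm(cfg: RunConfig) -> list[Path]:
    inputs, series = _load_series(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, runs = inputs["subjects"], inputs["runs"]

    std = {key: standardize(X) for key, X in series.items()}
    concat_per_subject = [np.vstack([std[(s, r)] for r in runs])
                          for s in subjects]

    written = []
    k = cfg.k
    if k is None:
        report = k_selection(concat_per_subject,
                             k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
                             n_repeats=cfg.k_repeats, seed=cfg.seed,
                             var_threshold=cfg.pca_var_threshold,
                             n_components=cfg.pca_components,
                             n_restarts=cfg.hmm_restarts,
                             max_iter=cfg.hmm_max_iter, tol=cfg.hmm_tol)
        k = report.chosen_k
        sp = out / "stability.json"
        _write_json(sp, {"chosen_k": report.chosen_k,
                         "composite": report.composite,
                         "zrand_mean": report.zrand_mean,
                         "nmi_mean": report.nmi_mean,
                         "concordance_mean": report.concordance_mean})
        written.append(sp)

    proj = pca_fit(np.vstack(concat_per_subject),
                   var_threshold=cfg.pca_var_threshold,
                   n_components=cfg.pca_components)
    reduced = {key: proj.transform(X) for key, X in std.items()}
    order = [(s, r) for s in subjects for r in runs]
    Y = np.vstack([reduced[key] for key in order])
    lengths = [len(reduced[key]) for key in order]
    model = hmm_fit(Y, k, lengths=lengths, seed=cfg.seed,
                    n_restarts=cfg.hmm_restarts, max_iter=cfg.hmm_max_iter,
                    tol=cfg.hmm_tol)

    mp = out / "hmm_model.json"
    _write_json(mp, {"K": model.K, "initial": model.initial.tolist(),
                     "transitions": model.transitions.tolist(),
                     "means": model.means.tolist(),
                     "covariances": model.covariances.tolist(),
                     "loglik": float(model.loglik_trace[-1]),
                     "pca_mean": proj.mean_vector.tolist(),
                     "pca_components": proj.components.tolist()})
    written.append(mp)

    for key in order:
        path = hmm_decode(model, reduced[key])
        df = pd.DataFrame({"state": path.viterbi})
        for kk in range(model.K):
            df[f"gamma_{kk}"] = path.gamma[:, kk]
        p = out / f"states_sub-{key[0]}_run-{key[1]}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
    return written


def _load_model(out: Path) -> tuple[HMMParams, np.ndarray, np.ndarray]:
    raw = json.loads(_require(out / "hmm_model.json", "hmm").read_text())
    model = HMMParams(K=raw["K"], initial=np.array(raw["initial"]),
                      transitions=np.array(raw["transitions"]),
                      means=np.array(raw["means"]),
                      covariances=np.array(raw["covariances"]))
    return model, np.array(raw["pca_mean"]), np.array(raw["pca_components"])


def _load_states(cfg: RunConfig, subjects, runs) -> dict[tuple[str, str], pd.DataFrame]:
    out = Path(cfg.out_dir)
    states = {}
    for s in subjects:
        for r in runs:
            p = _require(out / f"states_sub-{s}_run-{r}.tsv", "hmm")
            states[(s, r)] = pd.read_csv(p, sep="\t")
    return states


def stage_profiles(cfg: RunConfig) -> list[Path]:
    inputs, series = _load_series(cfg)
    out = Path(cfg.out_dir)
    model, *_ = _load_model(out)
    states = _load_states(cfg, inputs["subjects"], inputs["runs"])
    std = [np.vstack([standardize(series[(s, r)]) for r in inputs["runs"]])
           for s in inputs["subjects"]]
    labels = [np.concatenate([states[(s, r)]["state"].to_numpy()
                              for r in inputs["runs"]])
              for s in inputs["subjects"]]
    networks = None
    lookup = Path(cfg.data_dir) / "parcel_networks.tsv"
    if lookup.exists():
        networks = pd.read_csv(lookup, sep="\t")["network_17"].to_numpy()
    profiles = state_profiles(std, labels, model.K, networks=networks,
                              q=cfg.fdr_q)
    amap = pd.DataFrame({f"state_{p.state}": p.activation_map
                         for p in profiles})
    p1 = out / "activation_maps.tsv"
    amap.to_csv(p1, sep="\t", index=False, float_format="%.10g")
    summary = {str(p.state): {"n_trs": p.n_trs_used, "empty": p.empty,
                              "n_sig_connections": (int(p.contrast_sig.sum() // 2)
                                                    if p.contrast_sig is not None
                                                    else None)}
               for p in profiles}
    p2 = out / "state_profiles.json"
    _write_json(p2, summary)
    return [p1, p2]


def _windowed_dataset(cfg: RunConfig, run: str) -> list[WindowedFeatures]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    model, *_ = _load_model(out)
    app = pd.read_csv(_require(out / f"run-{run}_appetite.tsv", "ratings"),
                      sep="\t")["appetite_hrf"].to_numpy()
    states = _load_states(cfg, inputs["subjects"], [run])
    cov = (pd.read_csv(inputs["covariates"], sep="\t")
           .set_index("subject_id") if inputs["covariates"] else None)
    scheme = make_windows(len(app), cfg.window_length, cfg.window_step)
    dataset = []
    for s in inputs["subjects"]:
        labels = states[(s, run)]["state"].to_numpy()
        covs = {}
        if cov is not None:
            key = s if s in cov.index else f"sub-{s}"
            if key in cov.index:
                row = cov.loc[key]
                covs = {c: row[c] for c in ("age", "sex", "motion")
                        if c in row.index}
        dataset.append(windowed_features(labels, app, scheme, model.K,
                                         subject_id=str(s), run_id=str(run),
                                         covariates=covs))
    return dataset


def stage_align(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    written = []
    for run in inputs["runs"]:
        for wf in _windowed_dataset(cfg, run):
            df = pd.DataFrame(wf.FO,
                              columns=[f"fo_{k}" for k in range(wf.FO.shape[1])])
            df["target"] = wf.target
            p = out / f"windows_sub-{wf.subject_id}_run-{run}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
    return written


def stage_predict(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    grid = default_lambda_grid(cfg.lambda_grid_size)
    written = []
    datasets = {run: _windowed_dataset(cfg, run) for run in inputs["runs"]}
    results = {}
    for run, ds in datasets.items():
        res = loso_cv(ds, grid=grid, seed=cfg.seed)
        results[run] = res
        p = out / f"prediction_run-{run}.json"
        _write_json(p, {
            "individual_mean_r": res.individual_mean_r,
            "individual_se": res.individual_se,
            "group_r": res.group_r,
            "group_lambda": res.group_lambda,
            "per_subject_r": res.per_subject_r.tolist(),
            "final_weights": res.final_weights.tolist()})
        written.append(p)
    runs = inputs["runs"]
    if len(runs) >= 2:
        cross = {}
        for a, b in ((0, 1), (1, 0)):
            res = cross_generalize(datasets[runs[a]], datasets[runs[b]],
                                   results[runs[a]].group_lambda)
            cross[f"{runs[a]}->{runs[b]}"] = {
                "individual_mean_r": res.individual_mean_r,
                "group_r": res.group_r}
        p = out / "cross_generalization.json"
        _write_json(p, cross)
        written.append(p)
    return written


def stage_importance(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    written = []
    for run in inputs["runs"]:
        pred = json.loads(_require(out / f"prediction_run-{run}.json",
                                   "predict").read_text())
        ds = _windowed_dataset(cfg, run)
        imp = bootstrap_importance(ds, pred["group_lambda"],
                                   B=cfg.n_boot_importance, seed=cfg.seed,
                                   q=cfg.fdr_q)
        df = pd.DataFrame({"state": range(len(imp.mean)), "mean": imp.mean,
                           "sd": imp.sd, "z": imp.z, "p": imp.p,
                           "significant": imp.significant})
        p = out / f"importance_run-{run}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
    return written


def stage_express(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    model, *_ = _load_model(out)
    rows = []
    per_run_ds = {run: _windowed_dataset(cfg, run) for run in inputs["runs"]}
    for i, s in enumerate(inputs["subjects"]):
        for k in range(model.K):
            fo_runs = [per_run_ds[r][i].FO[:, k] for r in inputs["runs"]]
            tg_runs = [per_run_ds[r][i].target for r in inputs["runs"]]
            r_all = state_expression(fo_runs, tg_runs)
            row = {"subject_id": s, "state": k, "expression": r_all}
            for rr in inputs["runs"]:
                idx = inputs["runs"].index(rr)
                row[f"expression_run-{rr}"] = state_expression(
                    [fo_runs[idx]], [tg_runs[idx]])
            rows.append(row)
    df = pd.DataFrame(rows)
    p = out / "expression.tsv"
    df.to_csv(p, sep="\t", index=False, float_format="%.10g")
    return [p]


def _expression_state(cfg: RunConfig, out: Path) -> int:
    if cfg.expression_state is not None:
        return cfg.expression_state
    inputs = discover_inputs(cfg.data_dir)
    run0 = inputs["runs"][0]
    imp = pd.read_csv(_require(out / f"importance_run-{run0}.tsv",
                               "importance"), sep="\t")
    return int(imp.loc[imp["z"].idxmax(), "state"])


def stage_mediate(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    if inputs["covariates"] is None:
        raise FileNotFoundError("covariates.tsv required for mediation")
    cov = pd.read_csv(inputs["covariates"], sep="\t")
    expr = pd.read_csv(_require(out / "expression.tsv", "express"), sep="\t",
                       dtype={"subject_id": str})
    state = _expression_state(cfg, out)
    e = (expr[expr["state"] == state]
         .set_index("subject_id")["expression"])
    cov = cov.set_index("subject_id")
    cov.index = [str(i).replace("sub-", "") for i in cov.index]
    e.index = [str(i).replace("sub-", "") for i in e.index]
    common = [i for i in cov.index if i in e.index]
    med = mediation_bca(cov.loc[common, "bmi"].to_numpy(),
                        e.loc[common].to_numpy(),
                        cov.loc[common, "craving_post"].to_numpy(),
                        covariates=cov.loc[common, "age"].to_numpy(),
                        B=cfg.n_boot_mediation, seed=cfg.seed)
    r_bmi, p_bmi = partial_correlation(e.loc[common].to_numpy(),
                                       cov.loc[common, "bmi"].to_numpy(),
                                       cov.loc[common, "age"].to_numpy())
    p = out / "mediation.json"
    _write_json(p, {"state": state, "a": med.a, "b": med.b, "c": med.c,
                    "c_prime": med.c_prime, "indirect": med.indirect,
                    "ci": [med.ci_low, med.ci_high],
                    "prop_mediated": med.prop_mediated,
                    "significant": med.significant,
                    "full_mediation": med.full_mediation,
                    "expression_bmi_partial_r": r_bmi,
                    "expression_bmi_partial_p": p_bmi})
    return [p]


def stage_trajectories(cfg: RunConfig) -> list[Path]:
    inputs = discover_inputs(cfg.data_dir)
    out = Path(cfg.out_dir)
    cov = pd.read_csv(inputs["covariates"], sep="\t")
    months = cov[[f"bmi_m{m}" for m in range(1, 7)]].to_numpy()
    res = cluster_trajectories(months, k=2)
    expr = pd.read_csv(_require(out / "expression.tsv", "express"), sep="\t",
                       dtype={"subject_id": str})
    state = _expression_state(cfg, out)
    e = expr[expr["state"] == state].reset_index(drop=True)["expression"]
    t, p = compare_types(e.to_numpy()[res.kept], res.labels)
    labels_df = pd.DataFrame({"subject_id": cov["subject_id"].to_numpy()[res.kept],
                              "traj_cluster": res.labels})
    p1 = out / "trajectory_labels.tsv"
    labels_df.to_csv(p1, sep="\t", index=False)
    p2 = out / "trajectories.json"
    _write_json(p2, {"state": state, "db_by_k": res.db_by_k,
                     "ch_by_k": res.ch_by_k, "t": t, "p": p})
    return [p1, p2]


def stage_conditions(cfg: RunConfig) -> list[Path]:
    """Condition-wise FO comparison for a blocked validation task.

    Expects ``conditions_path`` to point at a TSV with one row per subject
    and one column per condition (mean FO of the state under test).
    """
    if cfg.conditions_path is None:
        raise FileNotFoundError("conditions_path not configured")
    df = pd.read_csv(cfg.conditions_path, sep="\t")
    cols = [c for c in df.columns if c != "subject_id"]
    res = condition_fo_compare(df[cols].to_numpy(), conditions=cols,
                               q=cfg.fdr_q)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = out / "conditions.json"
    _write_json(p, {"F": res.F, "p": res.p, "df": list(res.df),
                    "pairwise": res.pairwise.to_dict(orient="records")})
    return [p]


STAGES = {"ratings": stage_ratings, "hmm": stage_hmm,
          "profiles": stage_profiles, "align": stage_align,
          "predict": stage_predict, "importance": stage_importance,
          "express": stage_express, "mediate": stage_mediate,
          "trajectories": stage_trajectories}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline and write ``manifest.json``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGE_ORDER if stages is None else stages
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.digest(),
                "seed": cfg.seed, "version": __version__,
                "stages": {}, "artifacts": {}}
    for name in stages:
        t0 = time.perf_counter()
        written = STAGES[name](cfg)
        manifest["stages"][name] = {"seconds": time.perf_counter() - t0}
        for p in written:
            manifest["artifacts"][p.name] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    mp = out / "manifest.json"
    _write_json(mp, manifest)
    return mp
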