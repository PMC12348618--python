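"""Shared fixtures: small synthetic cohorts and a written-to-disk dataset."""

import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from statecue.synthetic import SynthConfig, gen_cohort, write_cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

logging.getLogger("statecue").setLevel(logging.ERROR)


SMALL = SynthConfig(n_subjects=8, n_raters=6, T_per_run=(120, 100), P=40,
                    K_true=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    return gen_cohort(SMALL)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size cohort used by the recovery experiments."""
    return gen_cohort(SynthConfig(seed=5))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(gen_cohort(SynthConfig(
        n_subjects=12, n_raters=6, T_per_run=(120, 100), P=40, K_true=3,
        seed=3)), d)
    return d


def light_run_config(data_dir, out_dir, seed=0):
    """Fast pipeline settings for the 12-subject on-disk cohort."""
    from statecue.pipeline import RunConfig
    return RunConfig(data_dir=str(data_dir), out_dir=str(out_dir), k=3,
                     k_repeats=3, pca_var_threshold=None, pca_components=10,
                     hmm_restarts=2, hmm_max_iter=30, hmm_tol=1e-4,
                     n_boot_importance=50, n_boot_mediation=200,
                     n_iter_reliability=200, seed=seed)


@pytest.fixture(scope="session")
def pipeline_run(cohort_dir, tmp_path_factory):
    """One full pipeline execution shared by the orchestration tests."""
    from statecue.pipeline import run_pipeline
    out = tmp_path_factory.mktemp("pipe")
    cfg = light_run_config(cohort_dir, out)
    manifest_path = run_pipeline(cfg)
    return cfg, manifest_path


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
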