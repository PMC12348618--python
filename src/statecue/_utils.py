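"""Shared helpers: deterministic RNG streams and small numeric utilities."""

from __future__ import annotations

import numpy as np

# Domain tags for per-entity RNG substreams.  Each (tag, index) pair maps to an
# independent generator regardless of cohort size, so subsets of a cohort are
# reproducible on their own.
DOMAIN_MODEL = 0
DOMAIN_GROUP = 1
DOMAIN_SUBJECT = 2
DOMAIN_RATER = 3
DOMAIN_COVARIATES = 4


def substream(seed: int, domain: int, index: int = 0) -> np.random.Generator:
    """Deterministic child generator for a (domain, index) pair under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(domain), int(index)))
    return np.random.default_rng(ss)


def zscore(x: np.ndarray, axis: int = 0, ddof: int = 0) -> np.ndarray:
    """Z-score along ``axis``. Raises on zero variance."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance slice cannot be z-scored")
    return (x - mu) / sd


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (same length as input)."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
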