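"""Sliding-window design: windowed fractional occupancies aligned with the
windowed group appetite target.

Windows are 0-based half-open TR intervals of fixed length (default 5 TRs)
advanced by a fixed step (default 2 TRs); trailing TRs not covered by a full
window are dropped so every FO denominator is constant.  The appetite target
is stimulus-locked: identical across subjects within a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import StatePath, fractional_occupancy
from .ratings import GroupAppetiteSeries


@dataclass
class WindowScheme:
    length_trs: int
    step_trs: int
    windows: list[tuple[int, int]]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class WindowedFeatures:
    subject_id: str
    run_id: str
    FO: np.ndarray      # W x K, rows on the simplex
    target: np.ndarray  # W-vector of windowed group appetite
    covariates: dict[str, float]


def make_windows(T: int, length: int = 5, step: int = 2) -> WindowScheme:
    """Half-open windows [i*step, i*step + length) fully inside [0, T)."""
    if length < 1 or step < 1:
        raise ValueError("length and step must be >= 1")
    if T < length:
        raise ValueError(f"series of {T} TRs is shorter than one window ({length})")
    n = (T - length) // step + 1
    windows = [(i * step, i * step + length) for i in range(n)]
    return WindowScheme(length_trs=length, step_trs=step, windows=windows)


def windowed_features(path: StatePath | np.ndarray,
                      appetite: GroupAppetiteSeries | np.ndarray,
                      scheme: WindowScheme, K: int,
                      subject_id: str = "", run_id: str = "",
                      covariates: dict[str, float] | None = None,
                      soft: bool = False) -> WindowedFeatures:
    """Per-window state FO (hard counts by default) and mean HRF-convolved
    group appetite."""
    labels = path.viterbi if isinstance(path, StatePath) else np.asarray(path)
    target_series = (appetite.hrf_convolved
                     if isinstance(appetite, GroupAppetiteSeries)
                     else np.asarray(appetite, float))
    if len(labels) != len(target_series):
        raise ValueError("state path and appetite series lengths differ")
    fo = np.empty((scheme.n_windows, K))
    tgt = np.empty(scheme.n_windows)
    for w, (a, b) in enumerate(scheme.windows):
        fo[w] = fractional_occupancy(path, K, interval=(a, b), soft=soft)
        tgt[w] = target_series[a:b].mean()
    return WindowedFeatures(subject_id=subject_id, run_id=run_id, FO=fo,
                            target=tgt, covariates=covariates or {})
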