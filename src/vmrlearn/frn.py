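"""Feedback-related negativity via the difference-wave approach.

Per-trial baseline correction (−200 to 0 ms), outcome classification from
the point system, class-wise ERP averaging, the success-minus-failure
difference wave, mean amplitude in the fixed 200–350 ms window, and
single-pass ±2 SD group-level outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .eeg import EpochedEEG

_TOL = 1e-9


@dataclass
class ERPSet:
    success_erp: np.ndarray
    failure_erp: np.ndarray
    difference_wave: np.ndarray  # success − failure, samplewise
    times: np.ndarray
    n_success: int
    n_failure: int


@dataclass
class FRNFeature:
    phase: str | None
    value_uv: float
    is_outlier: bool = False


def baseline_correct(epochs: EpochedEEG, baseline: tuple[float, float] = (-0.2, 0.0)) -> EpochedEEG:
    """Subtract each trial/channel's mean over the pre-onset baseline."""
    t = epochs.times
    lo, hi = baseline
    if lo < t[0] - _TOL or hi > t[-1] + 1.0 / epochs.srate + _TOL:
        raise ValueError("baseline interval outside the epoch")
    mask = (t >= lo - _TOL) & (t < hi - _TOL)
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    means = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.copy_with(epochs.data - means)


def classify_outcome(points: int, condition: str) -> str:
    """Success/failure label from per-trial points.

    Reward group: 4 points is a success, 0–3 a failure. Punishment group:
    0 points is a success, −4 to −1 a failure.
    """
    if condition == "reward":
        if points == 4:
            return "success"
        if 0 <= points <= 3:
            return "failure"
    elif condition == "punishment":
        if points == 0:
            return "success"
        if -4 <= points <= -1:
            return "failure"
    else:
        raise ValueError(f"unknown condition {condition!r}")
    raise ValueError(f"points {points} out of range for the {condition} condition")


def condition_erps(epochs: EpochedEEG, labels: Sequence[str] | None = None) -> ERPSet:
    """Class-wise trial-average ERPs and their difference wave.

    Expects single-channel (cluster-averaged) epochs. Labels default to the
    epoch set's own trial labels.
    """
    if epochs.data.shape[1] != 1:
        raise ValueError("condition_erps expects single-channel epochs; apply cluster_average first")
    labels = list(labels if labels is not None else (epochs.trial_labels or []))
    if len(labels) != epochs.n_trials:
        raise ValueError("label count does not match trial count")
    labels_arr = np.asarray(labels)
    succ = labels_arr == "success"
    fail = labels_arr == "failure"
    if not succ.any() or not fail.any():
        raise ValueError("both success and failure trials are required")
    s = epochs.data[succ, 0, :].mean(axis=0)
    f = epochs.data[fail, 0, :].mean(axis=0)
    return ERPSet(
        success_erp=s,
        failure_erp=f,
        difference_wave=s - f,
        times=epochs.times,
        n_success=int(succ.sum()),
        n_failure=int(fail.sum()),
    )


def frn_amplitude(erps: ERPSet, window: tuple[float, float] = (0.2, 0.35)) -> float:
    """Mean of the difference wave within the window (endpoints inclusive)."""
    lo, hi = window
    t = erps.times
    if lo < t[0] - _TOL or hi > t[-1] + _TOL:
        raise ValueError("FRN window outside the epoch")
    mask = (t >= lo - _TOL) & (t <= hi + _TOL)
    return float(erps.difference_wave[mask].mean())


def exclude_outliers(values: Sequence[float], k: float = 2.0) -> np.ndarray:
    """Retain-mask for values within mean ± k·SD of the full sample.

    Single pass: mean and sample SD (n−1) are computed once on all values;
    the mask is not recomputed on the retained subset. Zero variance
    retains everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier exclusion")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    mu = x.mean()
    return np.abs(x - mu) <= k * sd
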