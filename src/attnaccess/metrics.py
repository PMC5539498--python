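"""Trial- and subject-level attentional metrics.

For every 30 s task trial the attention stream is compared against a
threshold (50 % by default).  The metrics are:

* **SS** (successful score): percentage of valid seconds on the goal side
  of the threshold (strictly above in attention trials, strictly below in
  non-attention ones).
* **t_i** (initial time): seconds from trial onset to the first valid
  sample on the goal side (1-based: a crossing at the first sample is
  1 s).
* **t_s** (sustained time): mean length of the maximal runs of
  consecutive valid goal-side samples.

Per-trial averaged features feed the classifier: Set1 is the mean
attention alone, Set2 adds the theta/beta ratio and Set3 uses attention
plus every raw band (meditation excluded).  Averages are taken after an
interquartile-range outlier filter.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ATTENTION,
    NON_ATTENTION,
    Session,
    Trial,
    canonical_members,
)

FEATURE_SETS = ("set1", "set2", "set3")
DEFAULT_THRESHOLD = 50.0


def iqr_filter(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Drop values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation of order statistics; the original
    order of the retained values is preserved and refiltering is
    idempotent.  Fewer than 4 values are returned unfiltered with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn(
            f"iqr_filter needs >= 4 values (got {v.size}); returning unfiltered",
            stacklevel=2,
        )
        return v.copy()
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return v[(v >= lo) & (v <= hi)]


def _goal_mask(trial: Trial, threshold: float) -> np.ndarray:
    """Strict goal comparison; samples equal to the threshold fail."""
    if trial.trial_type == ATTENTION:
        return trial.attention > threshold
    if trial.trial_type == NON_ATTENTION:
        return trial.attention < threshold
    raise ValueError(f"trial_type {trial.trial_type!r} has no goal")


def successful_score(trial: Trial, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Percentage of valid seconds meeting the goal (NaN if none valid)."""
    valid = trial.valid
    if not valid.any():
        warnings.warn(
            f"trial {trial.trial_index} has no valid samples; SS undefined",
            stacklevel=2,
        )
        return float("nan")
    goal = _goal_mask(trial, threshold)
    return 100.0 * float((goal & valid).sum()) / float(valid.sum())


def initial_time(trial: Trial, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Seconds to the first valid goal-side sample (NaN if never reached)."""
    on_goal = _goal_mask(trial, threshold) & trial.valid
    idx = np.flatnonzero(on_goal)
    if idx.size == 0:
        return float("nan")
    return float(idx[0] + 1)


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True."""
    if not mask.any():
        return np.array([], dtype=int)
    padded = np.concatenate(([0], mask.astype(int), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def sustained_time(trial: Trial, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Mean maximal run length of consecutive valid goal-side samples."""
    runs = _run_lengths(_goal_mask(trial, threshold) & trial.valid)
    if runs.size == 0:
        return float("nan")
    return float(runs.mean())


def _mean_se(values: list[float]) -> tuple[float, float, int]:
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    if n == 1:
        return float(arr[0]), float("nan"), 1
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(n)), n


def subject_summary(
    sessions: Sequence[Session], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-condition summary over all of a subject's sessions.

    SS is pooled over all valid seconds of the condition; t_i and t_s are
    means over trials (trials where the metric is undefined are excluded)
    with SE = sample SD / sqrt(n of contributing trials).  Returns one
    row per condition with columns ss, t_i_mean, t_i_se, t_s_mean,
    t_s_se, n_trials, n_trials_t_i, n_trials_t_s.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    rows = []
    for condition in (ATTENTION, NON_ATTENTION):
        goal_sec = valid_sec = 0
        t_i_vals: list[float] = []
        t_s_vals: list[float] = []
        n_trials = 0
        for session in sessions:
            for trial in session.trials_of_type(condition):
                n_trials += 1
                goal = _goal_mask(trial, threshold) & trial.valid
                goal_sec += int(goal.sum())
                valid_sec += int(trial.valid.sum())
                t_i_vals.append(initial_time(trial, threshold))
                t_s_vals.append(sustained_time(trial, threshold))
        ss = 100.0 * goal_sec / valid_sec if valid_sec else float("nan")
        if valid_sec == 0:
            warnings.warn(f"no valid seconds for condition {condition}", stacklevel=2)
        t_i_mean, t_i_se, n_i = _mean_se(t_i_vals)
        t_s_mean, t_s_se, n_s = _mean_se(t_s_vals)
        rows.append(
            {
                "condition": condition,
                "ss": ss,
                "t_i_mean": t_i_mean,
                "t_i_se": t_i_se,
                "t_s_mean": t_s_mean,
                "t_s_se": t_s_se,
                "n_trials": n_trials,
                "n_trials_t_i": n_i,
                "n_trials_t_s": n_s,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def _filtered_mean(values: np.ndarray) -> float:
    if values.size == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept = iqr_filter(values)
    return float(kept.mean()) if kept.size else float("nan")


def filtered_band_means(trial: Trial, select: np.ndarray) -> np.ndarray:
    """IQR-filtered mean of every raw band over the selected samples."""
    return np.array(
        [_filtered_mean(trial.bands[select, b]) for b in range(trial.n_bands)]
    )


def theta_beta_ratio(trial: Trial, select: np.ndarray) -> float:
    """Ratio of the canonical theta and beta mean powers.

    Computed as ratio-of-(filtered)-means, aggregating sub-bands
    (low/high beta etc.) by averaging their filtered means.
    """
    members = canonical_members(trial.band_names)
    band_means = filtered_band_means(trial, select)
    theta = float(np.mean(band_means[members["theta"]]))
    beta = float(np.mean(band_means[members["beta"]]))
    if beta == 0 or np.isnan(beta):
        return float("nan")
    return theta / beta


def trial_average_features(
    trial: Trial,
    feature_set: str = "set1",
    window: tuple[float, float] | None = None,
) -> np.ndarray | None:
    """Per-trial averaged feature vector for one of the three sets.

    ``window`` is an optional ``(start_s, length_s)`` restriction inside
    the trial (used for the short training windows of the access
    analysis).  Each signal is IQR-filtered over the window's valid
    samples before averaging.  Returns None (with a warning) when no
    valid sample survives.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    n = trial.n_seconds
    select = trial.valid.copy()
    if window is not None:
        start, length = window
        if start < 0 or length <= 0 or start + length > n + 1e-9:
            raise ValueError(
                f"window {window} outside trial of {n} s"
            )
        t = np.arange(n)
        select &= (t >= start) & (t < start + length)
    if not select.any():
        warnings.warn(
            f"trial {trial.trial_index}: no valid samples in window; "
            "features undefined",
            stacklevel=2,
        )
        return None
    att = _filtered_mean(trial.attention[select])
    if feature_set == "set1":
        return np.array([att])
    if feature_set == "set2":
        return np.array([att, theta_beta_ratio(trial, select)])
    return np.concatenate([[att], filtered_band_means(trial, select)])


def feature_names(feature_set: str, band_names: Sequence[str]) -> tuple[str, ...]:
    if feature_set == "set1":
        return ("attention",)
    if feature_set == "set2":
        return ("attention", "theta_beta")
    return ("attention",) + tuple(band_names)
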