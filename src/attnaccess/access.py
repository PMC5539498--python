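"""Scanning-board access characterization.

A communication board is scanned icon by icon with period ``t_scan``; the
user selects by raising attention above the classifier's threshold and
holding it for a dwell window ``t_w``.  Three constraints tie the board
to the user's temporal behaviour (one-sided 95 % normal bounds on the
switching latencies):

* ``t_scan = (t_on_mean + 1.64 * t_on_sd) + t_w`` -- the scan period must
  cover the onset latency plus the dwell window;
* ``t_w > t_off_mean + 1.64 * t_off_sd`` -- the dwell window must outlast
  the release latency so the following icon is not selected;
* ``Np * (N_icons - 1) * t_scan < T_non_att`` -- spurious supra-threshold
  pulses of length >= t_w during the non-attention phase (Np per 30 s)
  must not produce false selections while the scan traverses the other
  icons.

The optimal dwell time is the smallest ``t_w`` on an integer grid (2..15 s,
capped by the cohort's typical sustained time) satisfying all three,
estimated per session from repeated balanced train/validation/test splits
(6/4/4 trials): the classifier is trained on the first ``t_w`` seconds of
the training trials, while validation/test features are extracted from a
``t_w`` window starting at the first second whose projection exceeds the
classifier threshold.  The information transfer rate uses the Wolpaw
bits-per-selection formula at the chosen dwell time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import FeatureVector, LdaModel, fit_lda, project
from .core import ATTENTION, NON_ATTENTION, Session, Trial, canonical_members
from .metrics import trial_average_features, _run_lengths

Z_95 = 1.64  # one-sided 95 % normal quantile, as used in the constraints
T_W_GRID = tuple(range(2, 16))


@dataclass
class LatencyStats:
    """Classifier-threshold switching latencies (means and sample SDs)."""

    t_on_mean: float
    t_on_sd: float
    t_off_mean: float
    t_off_sd: float
    n_on: int = 0
    n_off: int = 0
    n_on_missed: int = 0
    n_off_missed: int = 0


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated balanced splitting of one 14-trial session."""

    n_train: int = 6
    n_validation: int = 4
    n_test: int = 4
    repeats: int = 10
    t_w_grid: tuple[int, ...] = T_W_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train", "n_validation", "n_test"):
            if getattr(self, name) < 2 or getattr(self, name) % 2 != 0:
                raise ValueError(f"{name} must be an even count >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.t_w_grid or list(self.t_w_grid) != sorted(self.t_w_grid):
            raise ValueError("t_w_grid must be a non-empty ascending sequence")


@dataclass
class AccessParams:
    """One subject's operating point for a given feature set.

    ``t_w_opt`` is None when no grid value satisfies the constraints (the
    subject cannot reliably drive the board under this feature set).
    """

    feature_set: str
    n_icons: int
    t_w_opt: int | None
    accuracy_pct: float
    t_scan: float
    np_at_opt: float
    latency: LatencyStats
    itr_bits_per_min: float

    @property
    def feasible(self) -> bool:
        return self.t_w_opt is not None


# ---------------------------------------------------------------------------
# Windowed features and per-second projections
# ---------------------------------------------------------------------------

def train_window_features(
    trial: Trial, t_w: float, feature_set: str = "set1"
) -> np.ndarray | None:
    """Features averaged over the first ``t_w`` seconds of the trial."""
    t_w = min(t_w, trial.n_seconds)
    return trial_average_features(trial, feature_set, window=(0, t_w))


def _per_second_matrix(trial: Trial, feature_set: str) -> np.ndarray:
    """Single-sample feature vectors, one row per second (no IQR filter)."""
    if feature_set == "set1":
        return trial.attention[:, None]
    if feature_set == "set2":
        members = canonical_members(trial.band_names)
        theta = trial.bands[:, members["theta"]].mean(axis=1)
        beta = trial.bands[:, members["beta"]].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(beta > 0, theta / beta, np.nan)
        return np.column_stack([trial.attention, tb])
    return np.column_stack([trial.attention, trial.bands])


def per_second_scores(trial: Trial, model: LdaModel, feature_set: str) -> np.ndarray:
    """Projection score per second; NaN on invalid seconds."""
    mat = _per_second_matrix(trial, feature_set)
    scores = mat @ model.weights
    scores = np.where(trial.valid & ~np.isnan(scores), scores, np.nan)
    return scores


def eval_window_features(
    trial: Trial,
    model: LdaModel,
    t_w: float,
    feature_set: str = "set1",
) -> tuple[np.ndarray | None, int | None]:
    """Features for validation/test trials: window starts at the first
    second whose per-second projection exceeds the classifier threshold.

    Returns ``(features, window_start)``; both are None when no second
    crosses (the trial is then predicted non-attention) or when the
    window holds no valid sample.  ``window_start`` is a 0-based second;
    the window is truncated at the trial end.
    """
    scores = per_second_scores(trial, model, feature_set)
    above = np.flatnonzero(np.nan_to_num(scores, nan=-np.inf) > model.threshold)
    if above.size == 0:
        return None, None
    start = int(above[0])
    length = min(float(t_w), trial.n_seconds - start)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = trial_average_features(trial, feature_set, window=(start, length))
    if feats is None:
        return None, None
    return feats, start


def predict_trial(
    trial: Trial, model: LdaModel, t_w: float, feature_set: str = "set1"
) -> str:
    """Class prediction with the windowed evaluation rule."""
    feats, _ = eval_window_features(trial, model, t_w, feature_set)
    if feats is None:
        return NON_ATTENTION
    return ATTENTION if project(model, feats) > model.threshold else NON_ATTENTION


# ---------------------------------------------------------------------------
# Latencies and pulse counts
# ---------------------------------------------------------------------------

def first_crossing(
    trial: Trial, model: LdaModel, feature_set: str = "set1"
) -> float:
    """Seconds (1-based) to the first projection on the trial's target side
    of the classifier threshold: above for attention trials, below for
    non-attention ones.  NaN when the threshold is never crossed."""
    scores = per_second_scores(trial, model, feature_set)
    if trial.trial_type == ATTENTION:
        hit = np.nan_to_num(scores, nan=-np.inf) > model.threshold
    else:
        hit = np.nan_to_num(scores, nan=np.inf) < model.threshold
    idx = np.flatnonzero(hit)
    return float(idx[0] + 1) if idx.size else float("nan")


def _mean_sd(values: Sequence[float]) -> tuple[float, float, int, int]:
    arr = np.asarray(values, dtype=float)
    ok = arr[~np.isnan(arr)]
    missed = int(np.isnan(arr).sum())
    if ok.size == 0:
        return float("nan"), float("nan"), 0, missed
    sd = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    return float(ok.mean()), sd, int(ok.size), missed


def latency_stats(
    trials: Sequence[Trial], model: LdaModel, feature_set: str = "set1"
) -> LatencyStats:
    """Onset/release latency statistics over labelled trials.

    Trials that never cross the threshold are excluded from the mean/SD
    but counted in ``n_*_missed``.  A single contributing trial reports
    SD 0 by convention.  Raises when a trial type has no crossing trial
    at all.
    """
    t_on = [first_crossing(t, model, feature_set) for t in trials if t.trial_type == ATTENTION]
    t_off = [first_crossing(t, model, feature_set) for t in trials if t.trial_type == NON_ATTENTION]
    if not t_on or not t_off:
        raise ValueError("both trial types must be present")
    on_mean, on_sd, n_on, miss_on = _mean_sd(t_on)
    off_mean, off_sd, n_off, miss_off = _mean_sd(t_off)
    if n_on == 0:
        raise ValueError("no attention trial crossed the threshold")
    if n_off == 0:
        raise ValueError("no non-attention trial crossed the threshold")
    return LatencyStats(on_mean, on_sd, off_mean, off_sd, n_on, n_off, miss_on, miss_off)


def count_pulses(
    trial: Trial, model: LdaModel, t_w: float, feature_set: str = "set1"
) -> int:
    """Number of supra-threshold pulses of length >= t_w in a
    non-attention trial (maximal runs of consecutive valid seconds whose
    projection exceeds the threshold)."""
    if trial.trial_type != NON_ATTENTION:
        raise ValueError("pulse counting is defined on non-attention trials")
    scores = per_second_scores(trial, model, feature_set)
    above = np.nan_to_num(scores, nan=-np.inf) > model.threshold
    runs = _run_lengths(above)
    return int((runs >= t_w).sum())


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def tscan_min(stats: LatencyStats, t_w: float) -> float:
    """Minimal scan period: onset latency 95 % bound plus the dwell window."""
    return stats.t_on_mean + Z_95 * stats.t_on_sd + t_w


def feasible(
    t_w: float,
    stats: LatencyStats,
    np_pulses: float,
    n_icons: int,
    t_scan: float,
    t_non_att: float = 30.0,
) -> bool:
    """Both strict operating constraints: the dwell window outlasts the
    release latency bound, and spurious pulses cause no false selection
    while the scan passes the other icons."""
    if n_icons < 2:
        raise ValueError("a scanning board needs at least 2 icons")
    release_ok = t_w > stats.t_off_mean + Z_95 * stats.t_off_sd
    false_pos_ok = np_pulses * (n_icons - 1) * t_scan < t_non_att
    return bool(release_ok and false_pos_ok)


def first_feasible_window(
    rows: Iterable[tuple[int, LatencyStats, float]],
    n_icons: int,
    t_non_att: float = 30.0,
) -> tuple[int, float] | None:
    """First (ascending) grid value satisfying the constraints.

    ``rows`` yields (t_w, latency stats, mean pulse count) in ascending
    t_w order; returns (t_w_opt, t_scan) or None when nothing qualifies.
    """
    for t_w, stats, np_pulses in rows:
        t_scan = tscan_min(stats, t_w)
        if feasible(t_w, stats, np_pulses, n_icons, t_scan, t_non_att):
            return t_w, t_scan
    return None


# ---------------------------------------------------------------------------
# Session evaluation and the optimal-window search
# ---------------------------------------------------------------------------

@dataclass
class SessionEval:
    """Raw outcomes of the repeated splits of one session at one t_w."""

    val_accuracy: float
    test_accuracy: float
    t_on_values: list[float]
    t_off_values: list[float]
    np_values: list[float]


def _balanced_split(
    session: Session, protocol: EvalProtocol, rng: np.random.Generator
) -> tuple[list[Trial], list[Trial], list[Trial]]:
    att = session.trials_of_type(ATTENTION)
    non = session.trials_of_type(NON_ATTENTION)
    need = (protocol.n_train + protocol.n_validation + protocol.n_test) // 2
    if len(att) != len(non) or len(att) < need:
        raise ValueError(
            f"session must hold >= {need} trials per type and be balanced; "
            f"got {len(att)}/{len(non)}"
        )
    ia = rng.permutation(len(att))
    inon = rng.permutation(len(non))
    ht, hv = protocol.n_train // 2, protocol.n_validation // 2
    hs = protocol.n_test // 2
    train = [att[i] for i in ia[:ht]] + [non[i] for i in inon[:ht]]
    val = [att[i] for i in ia[ht : ht + hv]] + [non[i] for i in inon[ht : ht + hv]]
    test = (
        [att[i] for i in ia[ht + hv : ht + hv + hs]]
        + [non[i] for i in inon[ht + hv : ht + hv + hs]]
    )
    return train, val, test


def session_evaluation(
    session: Session,
    t_w: float,
    feature_set: str = "set1",
    protocol: EvalProtocol = EvalProtocol(),
) -> SessionEval:
    """Repeated 6/4/4 balanced splits of one session at one dwell time.

    Per repeat: fit on the first ``t_w`` seconds of the training trials,
    classify validation and test trials with the windowed evaluation
    rule, and collect per-trial latencies and pulse counts from the
    validation trials.  Accuracies are averaged over repeats; latencies
    and pulse counts are pooled.
    """
    correct_val = total_val = correct_test = total_test = 0
    t_on: list[float] = []
    t_off: list[float] = []
    np_vals: list[float] = []
    for r in range(protocol.repeats):
        rng = np.random.default_rng(
            [int(protocol.seed), int(session.session_index), r]
        )
        train, val, test = _balanced_split(session, protocol, rng)
        fvs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for trial in train:
                feats = train_window_features(trial, t_w, feature_set)
                if feats is not None and not np.any(np.isnan(feats)):
                    fvs.append(FeatureVector(feats, trial.trial_type))
        try:
            model = fit_lda(fvs)
        except ValueError:
            continue  # degenerate split; contributes nothing
        for trial in val:
            correct_val += predict_trial(trial, model, t_w, feature_set) == trial.trial_type
            total_val += 1
            t = first_crossing(trial, model, feature_set)
            if trial.trial_type == ATTENTION:
                t_on.append(t)
            else:
                t_off.append(t)
                np_vals.append(count_pulses(trial, model, t_w, feature_set))
        for trial in test:
            correct_test += predict_trial(trial, model, t_w, feature_set) == trial.trial_type
            total_test += 1
    if total_val == 0:
        raise ValueError("no evaluable split (all repeats degenerate)")
    return SessionEval(
        val_accuracy=100.0 * correct_val / total_val,
        test_accuracy=100.0 * correct_test / total_test,
        t_on_values=t_on,
        t_off_values=t_off,
        np_values=np_vals,
    )


def _aggregate(evals: Sequence[SessionEval]) -> tuple[float, float, LatencyStats, float]:
    val_acc = float(np.mean([e.val_accuracy for e in evals]))
    test_acc = float(np.mean([e.test_accuracy for e in evals]))
    t_on = [v for e in evals for v in e.t_on_values]
    t_off = [v for e in evals for v in e.t_off_values]
    np_vals = [v for e in evals for v in e.np_values]
    on_mean, on_sd, n_on, miss_on = _mean_sd(t_on)
    off_mean, off_sd, n_off, miss_off = _mean_sd(t_off)
    stats = LatencyStats(
        on_mean, on_sd, off_mean, off_sd, n_on, n_off, miss_on, miss_off
    )
    np_mean = float(np.mean(np_vals)) if np_vals else float("nan")
    return val_acc, test_acc, stats, np_mean


def optimal_window(
    sessions: Sequence[Session],
    feature_set: str = "set1",
    n_icons: int = 4,
    protocol: EvalProtocol = EvalProtocol(),
) -> AccessParams:
    """Ascending scan of the dwell-time grid; first feasible wins.

    Feasibility uses validation-set latency and pulse statistics pooled
    over sessions and repeats; the reported accuracy comes from the test
    trials at the chosen dwell time.  Returns the infeasible marker
    (``t_w_opt=None``) when no grid value qualifies.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    t_non_att = float(sessions[0].trials[0].n_seconds)
    last = None
    for t_w in protocol.t_w_grid:
        evals = [
            session_evaluation(s, t_w, feature_set, protocol) for s in sessions
        ]
        val_acc, test_acc, stats, np_mean = _aggregate(evals)
        last = (val_acc, test_acc, stats, np_mean)
        if math.isnan(stats.t_on_mean) or math.isnan(stats.t_off_mean):
            continue
        t_scan = tscan_min(stats, t_w)
        np_eff = 0.0 if math.isnan(np_mean) else np_mean
        if feasible(t_w, stats, np_eff, n_icons, t_scan, t_non_att):
            return AccessParams(
                feature_set=feature_set,
                n_icons=n_icons,
                t_w_opt=int(t_w),
                accuracy_pct=test_acc,
                t_scan=t_scan,
                np_at_opt=np_eff,
                latency=stats,
                itr_bits_per_min=itr(test_acc / 100.0, float(t_w)),
            )
    # infeasible: report the last grid point's statistics for context
    _, test_acc, stats, np_mean = last
    return AccessParams(
        feature_set=feature_set,
        n_icons=n_icons,
        t_w_opt=None,
        accuracy_pct=test_acc,
        t_scan=float("nan"),
        np_at_opt=np_mean,
        latency=stats,
        itr_bits_per_min=float("nan"),
    )


# ---------------------------------------------------------------------------
# Information transfer rate
# ---------------------------------------------------------------------------

def itr(accuracy: float, t_select: float, n_choices: int = 2) -> float:
    """Wolpaw information transfer rate in bits/min.

    Bits per selection B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)),
    with B = log2 N at P = 1 by continuity; ITR = B * 60 / t_select.
    Accuracies at or below chance are clamped to 0 bits/min.
    """
    if not (0.0 < accuracy <= 1.0):
        raise ValueError("accuracy must be in (0, 1]")
    if t_select <= 0:
        raise ValueError("t_select must be positive")
    if n_choices < 2:
        raise ValueError("n_choices must be >= 2")
    n = n_choices
    if accuracy <= 1.0 / n:
        warnings.warn("accuracy at or below chance: ITR clamped to 0", stacklevel=2)
        return 0.0
    if accuracy == 1.0:
        bits = math.log2(n)
    else:
        p = accuracy
        bits = math.log2(n) + p * math.log2(p) + (1 - p) * math.log2((1 - p) / (n - 1))
    return bits * 60.0 / t_select


def access_table(
    cohort: dict[str, list[Session]],
    feature_sets: Sequence[str] = ("set1", "set2", "set3"),
    n_icons: int = 4,
    protocol: EvalProtocol = EvalProtocol(),
) -> pd.DataFrame:
    """Operating-point report: one row per subject and feature set."""
    rows = []
    for subject_id, sessions in cohort.items():
        for fset in feature_sets:
            params = optimal_window(sessions, fset, n_icons, protocol)
            rows.append(
                {
                    "subject_id": subject_id,
                    "feature_set": fset,
                    "t_w_opt": params.t_w_opt,
                    "accuracy_pct": params.accuracy_pct,
                    "t_on_mean": params.latency.t_on_mean,
                    "t_on_sd": params.latency.t_on_sd,
                    "t_off_mean": params.latency.t_off_mean,
                    "t_off_sd": params.latency.t_off_sd,
                    "t_scan": params.t_scan,
                    "np_at_opt": params.np_at_opt,
                    "n_icons": n_icons,
                    "itr_bits_per_min": params.itr_bits_per_min,
                }
            )
    return pd.DataFrame(rows)
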