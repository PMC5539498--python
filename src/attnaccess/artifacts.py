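"""Two-feature artifact screening of raw 1 s epochs.

Each non-overlapping 512-sample epoch preceding an attention update is
summarized by two features: the peak-to-peak sample range (``MinMax``) and
the energy of the residual left after subtracting a Savitzky-Golay
smoothed version of the epoch (order 2, window 35) from the raw signal
(``ESF``).  Muscle bursts leave high-frequency energy the smoother cannot
follow (high ESF); blinks are large but slow (high MinMax, low ESF);
motion artifacts raise both.  Epochs are labelled by per-label threshold
boxes in this feature plane, and a second of the 1 Hz stream is admitted
only when the sensor reports good contact and its epoch is clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import Session, Trial

SG_WINDOW = 35
SG_ORDER = 2
EPOCH_SAMPLES = 512
_ADC_LIMIT = 2048  # 12-bit signed range after offset removal

CLEAN = "clean"
BLINK = "blink"
ARTIFACT_OTHER = "artifact_other"


@dataclass
class RawEpoch:
    """One second of raw signal: 512 signed integer ADC samples."""

    samples: np.ndarray
    start_second: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.shape[0] != EPOCH_SAMPLES:
            raise ValueError(
                f"epoch must hold exactly {EPOCH_SAMPLES} samples, "
                f"got shape {self.samples.shape}"
            )
        if np.any(np.abs(self.samples) > _ADC_LIMIT):
            raise ValueError("samples exceed the 12-bit signed range")


@dataclass(frozen=True)
class ArtifactFeatures:
    minmax: float
    esf: float

    def __post_init__(self) -> None:
        if self.minmax < 0 or self.esf < 0:
            raise ValueError("features must be non-negative")


@dataclass
class ThresholdBox:
    """Per-label (min, max) bounds on each feature dimension.

    ``bounds[label] = ((minmax_lo, minmax_hi), (esf_lo, esf_hi))``.
    Membership uses closed intervals on both dimensions.
    """

    bounds: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for label, dims in self.bounds.items():
            for lo, hi in dims:
                if lo > hi:
                    raise ValueError(f"box for {label!r} has min > max")

    def contains(self, label: str, features: ArtifactFeatures) -> bool:
        (mlo, mhi), (elo, ehi) = self.bounds[label]
        return mlo <= features.minmax <= mhi and elo <= features.esf <= ehi


def sg_residual(epoch: RawEpoch | np.ndarray) -> np.ndarray:
    """Raw minus Savitzky-Golay smoothed signal (order 2, window 35).

    The smoother fits a local quadratic by least squares over a centred
    35-sample window; edges use mirror padding.  Polynomials of degree
    <= 2 are reproduced exactly on interior samples, so the residual is
    zero there for such inputs.
    """
    x = epoch.samples if isinstance(epoch, RawEpoch) else np.asarray(epoch)
    x = x.astype(float)
    if x.shape[0] != EPOCH_SAMPLES:
        raise ValueError(f"epoch must hold {EPOCH_SAMPLES} samples")
    smoothed = savgol_filter(x, SG_WINDOW, SG_ORDER, mode="mirror")
    return x - smoothed


def epoch_features(epoch: RawEpoch | np.ndarray) -> ArtifactFeatures:
    """(MinMax, ESF) of one epoch."""
    x = epoch.samples if isinstance(epoch, RawEpoch) else np.asarray(epoch)
    residual = sg_residual(epoch)
    return ArtifactFeatures(
        minmax=float(np.max(x) - np.min(x)),
        esf=float(np.sum(residual**2)),
    )


def classify_epoch(features: ArtifactFeatures, box: ThresholdBox) -> str:
    """clean if inside the clean box; else blink if inside the blink box;
    else artifact_other."""
    if CLEAN not in box.bounds:
        raise ValueError("box is not calibrated (no clean bounds)")
    if box.contains(CLEAN, features):
        return CLEAN
    if BLINK in box.bounds and box.contains(BLINK, features):
        return BLINK
    return ARTIFACT_OTHER


def calibrate_box(
    labeled_epochs: Iterable[tuple[RawEpoch | np.ndarray, str]],
    q: float = 0.01,
) -> ThresholdBox:
    """Quantile threshold boxes from labelled training epochs.

    For each boxed label (clean, and blink when present) and each feature
    dimension, bounds are the [q, 1-q] empirical quantiles of that
    label's feature values.  The default q=0.01 yields a conservative
    clean box: borderline epochs are rejected rather than admitted.
    """
    if not (0.0 <= q < 0.5):
        raise ValueError("q must be in [0, 0.5)")
    feats: dict[str, list[ArtifactFeatures]] = {}
    for epoch, label in labeled_epochs:
        feats.setdefault(label, []).append(epoch_features(epoch))
    if CLEAN not in feats:
        raise ValueError("calibration requires labelled clean epochs")
    bounds = {}
    for label in (CLEAN, BLINK):
        if label not in feats:
            continue
        values = feats[label]
        if len(values) < 10:
            raise ValueError(
                f"need >= 10 labelled epochs for {label!r}, got {len(values)}"
            )
        mm = np.array([f.minmax for f in values])
        es = np.array([f.esf for f in values])
        bounds[label] = (
            (float(np.quantile(mm, q)), float(np.quantile(mm, 1 - q))),
            (float(np.quantile(es, q)), float(np.quantile(es, 1 - q))),
        )
    return ThresholdBox(bounds=bounds)


def screen_stream(
    session: Session,
    epochs: Sequence[RawEpoch | np.ndarray] | None,
    box: ThresholdBox | None = None,
) -> tuple[Session, pd.DataFrame]:
    """Gate the session's per-second validity flags.

    ``epochs`` is one raw epoch per task-trial second, in stream order
    (concatenation of the task halves), or None, in which case only the
    contact-quality flag gates validity.  Second ``t`` is valid iff its
    ``poor_signal`` is 0 and (no epochs were supplied or its epoch is
    labelled clean).  Invalid seconds are flagged, never deleted; gating
    can only shrink the valid set.  Returns the re-flagged session and a
    per-second report (second, poor_signal, label, valid).
    """
    total = session.task_seconds
    if epochs is not None:
        if box is None:
            raise ValueError("screening with epochs requires a calibrated box")
        if len(epochs) != total:
            raise ValueError(
                f"epoch/stream misalignment at index {min(len(epochs), total)}: "
                f"{len(epochs)} epochs for {total} stream seconds"
            )
    new_trials = []
    rows = []
    offset = 0
    for trial in session.trials:
        n = trial.n_seconds
        good_contact = trial.poor_signal == 0
        labels = [""] * n
        if epochs is None:
            clean_mask = np.ones(n, dtype=bool)
        else:
            clean_mask = np.zeros(n, dtype=bool)
            for i in range(n):
                label = classify_epoch(epoch_features(epochs[offset + i]), box)
                labels[i] = label
                clean_mask[i] = label == CLEAN
        valid = trial.valid & good_contact & clean_mask
        new_trials.append(trial.with_valid(valid))
        for i in range(n):
            rows.append(
                {
                    "second": offset + i,
                    "trial_index": trial.trial_index,
                    "poor_signal": int(trial.poor_signal[i]),
                    "label": labels[i],
                    "valid": bool(valid[i]),
                }
            )
        offset += n
    screened = replace(session, trials=new_trials)
    return screened, pd.DataFrame(rows)
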