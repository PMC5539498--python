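"""Core containers for the 1 Hz processed sensor stream.

The one-channel headset emits, once per second, an attention and a
meditation indicator (0-100 %), a vector of power-band values and a
contact-quality flag (``poor_signal``; 0 means usable).  A *trial* is the
30 s task half of a one-minute protocol slot, labelled ``attention`` or
``non_attention``; the relaxation half is kept separately and excluded
from analysis.  A *session* is the ordered collection of one day's trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

ATTENTION = "attention"
NON_ATTENTION = "non_attention"
REST = "rest"
TRIAL_TYPES = (ATTENTION, NON_ATTENTION)

#: Documented band order of the sensor's 8-band payload.
BAND_NAMES_8 = (
    "delta",
    "theta",
    "low_alpha",
    "high_alpha",
    "low_beta",
    "high_beta",
    "low_gamma",
    "mid_gamma",
)

#: 9-band variant (adds a high-gamma band at the end).
BAND_NAMES_9 = BAND_NAMES_8 + ("high_gamma",)

#: Canonical 5-band grouping used for the statistical comparisons.
CANONICAL_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def default_band_names(n_bands: int) -> tuple[str, ...]:
    """Band names for a given band count (generic names outside 8/9)."""
    if n_bands == 8:
        return BAND_NAMES_8
    if n_bands == 9:
        return BAND_NAMES_9
    return tuple(f"band_{i + 1}" for i in range(n_bands))


def canonical_members(band_names: Sequence[str]) -> dict[str, list[int]]:
    """Map each canonical band to the indices of its member sub-bands.

    ``low_alpha``/``high_alpha`` both belong to ``alpha``, and so on.
    Raises if a canonical band has no member (the grouping is then
    undefined for this band layout).
    """
    members: dict[str, list[int]] = {b: [] for b in CANONICAL_BANDS}
    for i, name in enumerate(band_names):
        for canon in CANONICAL_BANDS:
            if canon in name:
                members[canon].append(i)
                break
    missing = [b for b, idx in members.items() if not idx]
    if missing:
        raise ValueError(
            f"cannot map band names {tuple(band_names)} onto canonical bands; "
            f"missing {missing}"
        )
    return members


@dataclass
class Trial:
    """One 30 s task half (or rest half) of the 1 Hz stream.

    Arrays are aligned per second; ``valid`` marks seconds admitted for
    analysis (good contact and, when raw epochs were screened, a clean
    epoch).
    """

    subject_id: str
    session_index: int
    trial_index: int
    trial_type: str
    attention: np.ndarray
    meditation: np.ndarray
    bands: np.ndarray
    poor_signal: np.ndarray
    valid: np.ndarray
    band_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.attention = np.asarray(self.attention, dtype=float)
        self.meditation = np.asarray(self.meditation, dtype=float)
        self.bands = np.atleast_2d(np.asarray(self.bands, dtype=float))
        self.poor_signal = np.asarray(self.poor_signal, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.attention.shape[0]
        if self.trial_type not in TRIAL_TYPES + (REST,):
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        for name, arr in (
            ("meditation", self.meditation),
            ("poor_signal", self.poor_signal),
            ("valid", self.valid),
        ):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n}")
        if self.bands.shape[0] != n:
            raise ValueError(f"bands rows {self.bands.shape[0]} != {n}")
        if not self.band_names:
            self.band_names = default_band_names(self.bands.shape[1])
        elif len(self.band_names) != self.bands.shape[1]:
            raise ValueError("band_names length does not match bands columns")
        if np.any((self.attention < 0) | (self.attention > 100)):
            raise ValueError("attention values outside [0, 100]")
        if np.any((self.meditation < 0) | (self.meditation > 100)):
            raise ValueError("meditation values outside [0, 100]")

    @property
    def n_seconds(self) -> int:
        return self.attention.shape[0]

    @property
    def n_bands(self) -> int:
        return self.bands.shape[1]

    def with_valid(self, valid: np.ndarray) -> "Trial":
        return replace(self, valid=np.asarray(valid, dtype=bool).copy())


@dataclass
class Session:
    """One recording session: alternating task trials plus rest halves."""

    subject_id: str
    session_index: int
    trials: list[Trial]
    rest: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, trial in enumerate(self.trials):
            expected = ATTENTION if i % 2 == 0 else NON_ATTENTION
            if trial.trial_type != expected:
                raise ValueError(
                    f"trial {i + 1} has type {trial.trial_type!r}, "
                    f"expected {expected!r} (alternation starts with attention)"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_of_type(self, trial_type: str) -> list[Trial]:
        return [t for t in self.trials if t.trial_type == trial_type]

    @property
    def task_seconds(self) -> int:
        return sum(t.n_seconds for t in self.trials)


def sessions_equal(a: Session, b: Session) -> bool:
    """Structural equality of two sessions (exact array comparison)."""
    if (a.subject_id, a.session_index) != (b.subject_id, b.session_index):
        return False
    if len(a.trials) != len(b.trials) or len(a.rest) != len(b.rest):
        return False
    for ta, tb in zip(a.trials + a.rest, b.trials + b.rest):
        if (ta.trial_type, ta.trial_index, ta.band_names) != (
            tb.trial_type,
            tb.trial_index,
            tb.band_names,
        ):
            return False
        if not (
            np.array_equal(ta.attention, tb.attention)
            and np.array_equal(ta.meditation, tb.meditation)
            and np.array_equal(ta.bands, tb.bands)
            and np.array_equal(ta.poor_signal, tb.poor_signal)
            and np.array_equal(ta.valid, tb.valid)
        ):
            return False
    return True
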