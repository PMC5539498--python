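"""Session CSV dialect and run configuration.

One row per second: ``subject_id, session_index, trial_index,
trial_type, t_in_trial, poor_signal, attention, meditation,
band_1..band_N, valid``.  Trial types alternate attention /
non_attention with the interleaved rest halves carried as ``rest`` rows.
Files written by :func:`write_session_csv` round-trip byte-identically
through :func:`read_session_csv`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .access import EvalProtocol
from .core import REST, Session, Trial, default_band_names

log = logging.getLogger("attnaccess")

_FIXED_COLUMNS = [
    "subject_id",
    "session_index",
    "trial_index",
    "trial_type",
    "t_in_trial",
    "poor_signal",
    "attention",
    "meditation",
]
_FLOAT_FORMAT = "%.8g"


def sessions_to_frame(sessions: list[Session]) -> pd.DataFrame:
    """Flatten sessions into the one-row-per-second table."""
    frames = []
    for session in sessions:
        rest_by_index = {t.trial_index: t for t in session.rest}
        blocks = []
        for trial in session.trials:
            blocks.append(trial)
            if trial.trial_index in rest_by_index:
                blocks.append(rest_by_index[trial.trial_index])
        for trial in blocks:
            n = trial.n_seconds
            data = {
                "subject_id": trial.subject_id,
                "session_index": session.session_index,
                "trial_index": trial.trial_index,
                "trial_type": trial.trial_type,
                "t_in_trial": np.arange(n),
                "poor_signal": trial.poor_signal,
                "attention": trial.attention,
                "meditation": trial.meditation,
            }
            for b in range(trial.n_bands):
                data[f"band_{b + 1}"] = trial.bands[:, b]
            data["valid"] = trial.valid.astype(int)
            frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def write_session_csv(sessions: list[Session], path: str | Path) -> None:
    df = sessions_to_frame(sessions)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def frame_to_sessions(df: pd.DataFrame) -> list[Session]:
    """Rebuild Session objects from the flat table (rows in file order)."""
    band_cols = sorted(
        (c for c in df.columns if c.startswith("band_")),
        key=lambda c: int(c.split("_")[1]),
    )
    n_bands = len(band_cols)
    band_names = default_band_names(n_bands)
    sessions = []
    for (sid, sidx), g in df.groupby(["subject_id", "session_index"], sort=False):
        trials, rests = [], []
        for (tidx, ttype), tg in g.groupby(["trial_index", "trial_type"], sort=False):
            tg = tg.sort_values("t_in_trial")
            t_in = tg["t_in_trial"].to_numpy()
            if not np.array_equal(t_in, np.arange(len(t_in))):
                raise ValueError(
                    f"t_in_trial not contiguous for subject {sid} session {sidx} "
                    f"trial {tidx} ({ttype})"
                )
            trial = Trial(
                subject_id=str(sid),
                session_index=int(sidx),
                trial_index=int(tidx),
                trial_type=str(ttype),
                attention=tg["attention"].to_numpy(),
                meditation=tg["meditation"].to_numpy(),
                bands=tg[band_cols].to_numpy(),
                poor_signal=tg["poor_signal"].to_numpy(),
                valid=tg["valid"].to_numpy().astype(bool),
                band_names=band_names,
            )
            (rests if ttype == REST else trials).append(trial)
        trials.sort(key=lambda t: t.trial_index)
        rests.sort(key=lambda t: t.trial_index)
        sessions.append(
            Session(
                subject_id=str(sid),
                session_index=int(sidx),
                trials=trials,
                rest=rests,
            )
        )
    return sessions


def read_session_csv(path: str | Path) -> list[Session]:
    """Parse and validate a session CSV.

    Structural problems (missing columns, non-numeric fields, duplicated
    per-second keys) raise with the offending row numbers; rows violating
    value ranges are dropped with a logged warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FIXED_COLUMNS + ["valid"] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    band_cols = [c for c in df.columns if c.startswith("band_")]
    numeric_cols = [
        "session_index",
        "trial_index",
        "t_in_trial",
        "poor_signal",
        "attention",
        "meditation",
        "valid",
    ] + band_cols
    if df.empty:
        warnings.warn(f"{path}: empty session file (header only)", stacklevel=2)
        return []
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"non-numeric values in column {col!r} at rows {list(bad + 2)}"
            )
        df[col] = coerced
    key = ["subject_id", "session_index", "trial_index", "trial_type", "t_in_trial"]
    dup = df.index[df.duplicated(key)]
    if len(dup) > 0:
        raise ValueError(f"duplicated per-second keys at rows {list(dup + 2)}")
    in_range = (
        df["attention"].between(0, 100)
        & df["meditation"].between(0, 100)
        & df["trial_type"].isin(["attention", "non_attention", "rest"])
    )
    for col in band_cols:
        in_range &= df[col] > 0
    rejected = df.index[~in_range]
    if len(rejected) > 0:
        # keep the seconds (trial timelines stay contiguous) but reject
        # their values: flag invalid and clamp into the legal ranges
        log.warning(
            "%s: rejected %d out-of-range rows, flagged invalid (rows %s)",
            path,
            len(rejected),
            list(rejected + 2)[:20],
        )
        df = df.copy()
        df.loc[rejected, "valid"] = 0
        df.loc[rejected, "attention"] = df.loc[rejected, "attention"].clip(0, 100)
        df.loc[rejected, "meditation"] = df.loc[rejected, "meditation"].clip(0, 100)
        for col in band_cols:
            df.loc[rejected, col] = df.loc[rejected, col].clip(lower=np.nextafter(0, 1))
    return frame_to_sessions(df)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; all randomness flows from ``seed``."""

    out_dir: str = "attnaccess_out"
    input_csv: str | None = None  # None -> generate the demo cohort
    seed: int = 0
    threshold: float = 50.0
    feature_sets: tuple[str, ...] = ("set1", "set2", "set3")
    n_icons: int = 4
    k_folds: int = 4
    n_bands: int = 8
    alpha: float = 0.05
    screen_epochs: bool = True
    protocol: EvalProtocol = field(default_factory=EvalProtocol)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        protocol_kwargs = raw.pop("protocol", {})
        cfg = cls(**raw)
        if protocol_kwargs:
            cfg.protocol = EvalProtocol(**protocol_kwargs)
        return cfg
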