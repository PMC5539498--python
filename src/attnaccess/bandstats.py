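"""Per-subject rank tests across trial types and survey aggregation.

For each subject, per-trial (IQR-filtered) means of the attention level,
the five canonical power bands and the theta/beta ratio are compared
between attention and non-attention trials with the two-sided
Mann-Whitney-Wilcoxon rank-sum test.  With the full protocol this is 70
trial means per subject (5 sessions x 7 trials x 2 types).  No
multiple-testing correction is applied across the seven variables: raw
p-values are reported, as is conventional for this per-subject
descriptive use; interpret them accordingly.

The end-of-session survey (three questions, ratings 1-3) is aggregated to
per-subject means across sessions and per-group means across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ATTENTION, NON_ATTENTION, Session, canonical_members
from .metrics import iqr_filter, theta_beta_ratio, filtered_band_means

#: Fixed variable order of the statistical reports.
VARIABLES = ("attention", "delta", "theta", "alpha", "beta", "gamma", "theta_beta")

EXACT_N_MAX = 20


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact enumeration when both samples have <= 20 observations and the
    pooled data is tie-free; otherwise the normal approximation with
    continuity and tie correction (ties get mid-ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if max(x.size, y.size) <= EXACT_N_MAX and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def build_trial_matrix(sessions: Sequence[Session]) -> pd.DataFrame:
    """One row per task trial: type plus IQR-filtered trial means.

    Columns: trial_type, attention, the five canonical bands, and
    theta_beta (ratio of filtered canonical means).
    """
    rows = []
    for session in sessions:
        for trial in session.trials:
            members = canonical_members(trial.band_names)
            select = trial.valid
            if not select.any():
                continue
            band_means = filtered_band_means(trial, select)
            att = iqr_filter(trial.attention[select])
            row = {
                "subject_id": trial.subject_id,
                "session_index": session.session_index,
                "trial_index": trial.trial_index,
                "trial_type": trial.trial_type,
                "attention": float(att.mean()) if att.size else float("nan"),
            }
            for canon, idx in members.items():
                row[canon] = float(np.mean(band_means[idx]))
            row["theta_beta"] = theta_beta_ratio(trial, select)
            rows.append(row)
    return pd.DataFrame(rows)


def _split_classes(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    att = matrix[matrix["trial_type"] == ATTENTION]
    non = matrix[matrix["trial_type"] == NON_ATTENTION]
    if len(att) == 0 or len(non) == 0:
        raise ValueError("both trial types must be present")
    if len(att) != len(non):
        raise ValueError(
            f"unbalanced classes: {len(att)} attention vs {len(non)} non-attention"
        )
    return att, non


def significance_table(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rank-sum p-value per variable, attention vs non-attention trials."""
    att, non = _split_classes(matrix)
    rows = []
    for var in VARIABLES:
        p = rank_sum_test(att[var].to_numpy(), non[var].to_numpy())
        rows.append({"variable": var, "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("variable")


def effect_directions(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Direction of significant class differences per variable.

    Non-significant variables (and exact mean ties) report ``none``.
    """
    table = significance_table(matrix, alpha)
    att, non = _split_classes(matrix)
    directions = []
    for var in VARIABLES:
        direction = "none"
        if table.loc[var, "significant"]:
            ma, mn = att[var].mean(), non[var].mean()
            if ma > mn:
                direction = "higher_in_attention"
            elif ma < mn:
                direction = "lower_in_attention"
        directions.append(direction)
    table = table.copy()
    table["direction"] = directions
    return table


# ---------------------------------------------------------------------------
# Survey aggregation
# ---------------------------------------------------------------------------

RATINGS = (1, 2, 3)
QUESTIONS = ("q_a", "q_b", "q_c")


@dataclass(frozen=True)
class SurveyResponse:
    """One session's three Likert ratings (1 no/badly, 2 neutral, 3 yes/well)."""

    subject_id: str
    session_index: int
    q_a: int
    q_b: int
    q_c: int

    def __post_init__(self) -> None:
        for q in QUESTIONS:
            if getattr(self, q) not in RATINGS:
                raise ValueError(f"{q} rating must be one of {RATINGS}")


def survey_subject_means(responses: Sequence[SurveyResponse]) -> pd.DataFrame:
    """Per-subject mean rating across sessions, one row per subject."""
    if not responses:
        raise ValueError("at least one response is required")
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                **{q: getattr(r, q) for q in QUESTIONS},
            }
            for r in responses
        ]
    )
    return df.groupby("subject_id")[list(QUESTIONS)].mean()


def survey_group_means(
    subject_means: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group mean of the per-subject means (not pooled sessions)."""
    groups = subject_means.index.map(lambda s: grouping[s])
    return subject_means.groupby(groups).mean()


def survey_aggregate(
    responses: Sequence[SurveyResponse], grouping: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-subject means, per-group means) of the survey ratings."""
    subject_means = survey_subject_means(responses)
    return subject_means, survey_group_means(subject_means, grouping)
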