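"""Attentional metrics: SS, initial/sustained times, IQR filter, features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnaccess.core import ATTENTION, NON_ATTENTION
from attnaccess.metrics import (
    initial_time,
    iqr_filter,
    subject_summary,
    successful_score,
    sustained_time,
    trial_average_features,
)

from conftest import make_trial


class TestIqrFilter:
    def test_zero_iqr_keeps_equal_values(self):
        assert list(iqr_filter([5, 5, 5, 5])) == [5, 5, 5, 5]

    def test_removes_gross_outlier(self):
        # Q1=2, Q3=4, IQR=2 -> bounds [-1, 7]
        assert list(iqr_filter([1, 2, 3, 4, 100])) == [1, 2, 3, 4]

    def test_short_input_unfiltered_with_warning(self):
        with pytest.warns(UserWarning, match=">= 4"):
            out = iqr_filter([1.0, 1000.0])
        assert list(out) == [1.0, 1000.0]

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=50,
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_subsequence_within_bounds(self, values):
        out = iqr_filter(values)
        # output is a subsequence of the input (order preserved)
        pos = 0
        for v in out:
            while pos < len(values) and values[pos] != v:
                pos += 1
            assert pos < len(values)
            pos += 1
        # retained values sit inside the fence computed from the input
        q1, q3 = np.quantile(values, [0.25, 0.75])
        iqr = q3 - q1
        assert np.all((out >= q1 - 1.5 * iqr) & (out <= q3 + 1.5 * iqr))
        # refiltering can only shrink further, never re-admit
        if out.size >= 4:
            again = iqr_filter(out)
            assert again.size <= out.size


class TestSuccessfulScore:
    def test_perfect_attention_trial(self):
        assert successful_score(make_trial([100.0] * 30)) == 100.0

    def test_high_attention_in_non_attention_trial_scores_zero(self):
        trial = make_trial([100.0] * 30, trial_type=NON_ATTENTION)
        assert successful_score(trial) == 0.0

    def test_partial_counts_only_valid_seconds(self):
        att = np.array([60.0] * 18 + [40.0] * 12)
        assert successful_score(make_trial(att)) == 60.0

    def test_threshold_equality_fails_the_goal(self):
        assert successful_score(make_trial([50.0] * 10)) == 0.0

    def test_no_valid_samples_is_nan(self):
        trial = make_trial([60.0] * 5, valid=[False] * 5)
        with pytest.warns(UserWarning):
            assert np.isnan(successful_score(trial))

    def test_order_free(self):
        rng = np.random.default_rng(0)
        att = rng.uniform(0, 100, 30)
        shuffled = rng.permutation(att)
        assert successful_score(make_trial(att)) == successful_score(
            make_trial(shuffled)
        )


class TestInitialTime:
    def test_immediate_crossing_is_one_second(self):
        assert initial_time(make_trial([60.0] + [40.0] * 29)) == 1.0

    def test_never_crossing_is_nan(self):
        assert np.isnan(initial_time(make_trial([40.0] * 30)))

    def test_third_sample_crossing(self):
        assert initial_time(make_trial([40.0, 45.0, 55.0] + [55.0] * 27)) == 3.0

    def test_invalid_samples_are_skipped(self):
        valid = [False, True, True]
        assert initial_time(make_trial([90.0, 40.0, 60.0], valid=valid)) == 3.0

    def test_not_order_free(self):
        a = make_trial([40.0, 60.0, 40.0])
        b = make_trial([40.0, 40.0, 60.0])
        assert initial_time(a) != initial_time(b)


class TestSustainedTime:
    def test_single_full_run(self):
        assert sustained_time(make_trial([80.0] * 30)) == 30.0

    def test_mean_of_runs(self):
        att = [80.0] * 10 + [20.0] * 5 + [80.0] * 5 + [20.0] * 10
        assert sustained_time(make_trial(att)) == 7.5

    def test_alternating_unit_runs(self):
        att = [80.0, 20.0] * 15
        assert sustained_time(make_trial(att)) == 1.0

    def test_never_reached_is_nan(self):
        assert np.isnan(sustained_time(make_trial([20.0] * 30)))

    def test_bounded_by_trial_duration(self, noisy_sessions):
        for session in noisy_sessions:
            for trial in session.trials:
                ts = sustained_time(trial)
                ti = initial_time(trial)
                if not np.isnan(ts):
                    assert 0 < ts <= trial.n_seconds
                if not np.isnan(ti):
                    assert 0 < ti <= trial.n_seconds


class TestSubjectSummary:
    def test_ideal_subject_theoretical_values(self, ideal_sessions):
        summary = subject_summary(ideal_sessions)
        for condition in (ATTENTION, NON_ATTENTION):
            row = summary.loc[condition]
            assert row["ss"] == 100.0
            assert row["t_i_mean"] == 1.0
            assert row["t_s_mean"] == 30.0
            assert row["t_i_se"] == 0.0
            assert row["n_trials"] == 35

    def test_latency_recovery(self):
        """Recovered onset latency ~ tau + 1 s within 2 SE over 35 trials."""
        from attnaccess.synthetic import SimConfig, SubjectProfile, generate_cohort

        profile = SubjectProfile(
            "lat",
            mu_att=75.0,
            mu_non=25.0,
            sigma_within=10.0,
            ar_coeff=0.5,
            tau_on=2.0,
            tau_off=3.0,
            poor_signal_rate=0.0,
        )
        sessions = generate_cohort([profile], SimConfig(seed=11))["lat"]
        summary = subject_summary(sessions)
        for condition, tau in ((ATTENTION, 2.0), (NON_ATTENTION, 3.0)):
            row = summary.loc[condition]
            assert abs(row["t_i_mean"] - (tau + 1.0)) <= 2.0 * row["t_i_se"]

    def test_single_trial_se_is_nan(self):
        from attnaccess.core import Session

        trials = [
            make_trial([80.0] * 30, ATTENTION, trial_index=1),
            make_trial([20.0] * 30, NON_ATTENTION, trial_index=2),
        ]
        session = Session("T", 1, trials)
        summary = subject_summary([session])
        assert np.isnan(summary.loc[ATTENTION, "t_i_se"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            subject_summary([])


class TestTrialAverageFeatures:
    def test_constant_attention_set1(self):
        feats = trial_average_features(make_trial([70.0] * 30), "set1")
        assert feats.shape == (1,) and feats[0] == 70.0

    def test_set3_length_with_nine_bands(self):
        trial = make_trial([70.0] * 30, n_bands=9)
        feats = trial_average_features(trial, "set3")
        assert feats.shape == (10,)

    def test_set2_theta_beta_ratio(self):
        n = 30
        bands = np.full((n, 8), 100.0)
        bands[:, 1] = 300.0  # theta
        bands[:, 4] = 100.0  # low beta
        bands[:, 5] = 200.0  # high beta
        trial = make_trial([70.0] * n, bands=bands)
        feats = trial_average_features(trial, "set2")
        assert np.isclose(feats[1], 300.0 / 150.0)

    def test_window_changes_mean_on_ramp(self):
        att = np.linspace(10, 90, 30)
        trial = make_trial(att)
        short = trial_average_features(trial, "set1", window=(0, 2))
        full = trial_average_features(trial, "set1")
        assert short[0] < full[0]

    def test_window_irrelevant_on_constant_trace(self):
        trial = make_trial([55.0] * 30)
        a = trial_average_features(trial, "set1", window=(0, 5))
        b = trial_average_features(trial, "set1")
        assert a[0] == b[0]

    def test_empty_window_returns_none(self):
        trial = make_trial([70.0] * 30, valid=[False] * 30)
        with pytest.warns(UserWarning):
            assert trial_average_features(trial, "set1") is None

    def test_window_outside_trial_rejected(self):
        with pytest.raises(ValueError, match="window"):
            trial_average_features(make_trial([70.0] * 30), "set1", window=(25, 10))
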