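"""Access model: windowed features, latencies, pulses, constraints, ITR."""

import numpy as np
import pytest

from attnaccess.access import (
    EvalProtocol,
    LatencyStats,
    count_pulses,
    eval_window_features,
    feasible,
    first_feasible_window,
    itr,
    latency_stats,
    optimal_window,
    session_evaluation,
    train_window_features,
    tscan_min,
)
from attnaccess.classify import FeatureVector, fit_lda
from attnaccess.core import ATTENTION, NON_ATTENTION
from attnaccess.synthetic import SimConfig, SubjectProfile, generate_cohort

from conftest import make_trial


@pytest.fixture(scope="module")
def simple_model():
    """1-D attention model with threshold at 50."""
    return fit_lda(
        [
            FeatureVector(np.array([80.0]), ATTENTION),
            FeatureVector(np.array([82.0]), ATTENTION),
            FeatureVector(np.array([20.0]), NON_ATTENTION),
            FeatureVector(np.array([18.0]), NON_ATTENTION),
        ]
    )


class TestWindowFeatures:
    def test_full_window_equals_full_trial(self):
        rng = np.random.default_rng(0)
        trial = make_trial(rng.uniform(20, 80, 30))
        full = train_window_features(trial, 30.0)
        from attnaccess.metrics import trial_average_features

        assert np.allclose(full, trial_average_features(trial, "set1"))

    def test_constant_trace_window_free(self):
        trial = make_trial([66.0] * 30)
        assert train_window_features(trial, 2.0)[0] == 66.0
        assert train_window_features(trial, 15.0)[0] == 66.0

    def test_ramp_short_window_smaller_mean(self):
        trial = make_trial(np.linspace(10, 90, 30))
        assert train_window_features(trial, 2.0)[0] < train_window_features(trial, 15.0)[0]


class TestEvalWindowFeatures:
    def test_constant_high_trace_starts_first_second(self, simple_model):
        trial = make_trial([90.0] * 30)
        feats, start = eval_window_features(trial, simple_model, 4.0)
        assert start == 0
        assert np.isclose(feats[0], 90.0)

    def test_never_crossing_defaults_to_non_attention(self, simple_model):
        from attnaccess.access import predict_trial

        trial = make_trial([10.0] * 30, trial_type=NON_ATTENTION)
        feats, start = eval_window_features(trial, simple_model, 4.0)
        assert feats is None and start is None
        assert predict_trial(trial, simple_model, 4.0) == NON_ATTENTION

    def test_crossing_at_second_seven(self, simple_model):
        att = np.array([30.0] * 7 + [70.0, 72.0, 74.0, 76.0] + [30.0] * 19)
        trial = make_trial(att)
        feats, start = eval_window_features(trial, simple_model, 4.0)
        assert start == 7
        assert np.isclose(feats[0], np.mean([70.0, 72.0, 74.0, 76.0]))


class TestLatencyStats:
    def test_ideal_zero_latency(self, simple_model, ideal_sessions):
        stats = latency_stats(ideal_sessions[0].trials, simple_model)
        assert stats.t_on_mean == 1.0 and stats.t_on_sd == 0.0
        assert stats.t_off_mean == 1.0 and stats.t_off_sd == 0.0

    def test_latency_recovery_against_generator(self, simple_model):
        profile = SubjectProfile(
            "lat2",
            mu_att=75.0,
            mu_non=25.0,
            sigma_within=10.0,
            ar_coeff=0.5,
            tau_on=3.0,
            tau_off=2.0,
            poor_signal_rate=0.0,
        )
        sessions = generate_cohort([profile], SimConfig(seed=21))["lat2"]
        trials = [t for s in sessions for t in s.trials]
        stats = latency_stats(trials, simple_model)
        se_on = stats.t_on_sd / np.sqrt(stats.n_on)
        assert abs(stats.t_on_mean - 4.0) <= 2 * se_on

    def test_single_trial_sd_zero(self, simple_model):
        trials = [
            make_trial([90.0] * 30, ATTENTION),
            make_trial([10.0] * 30, NON_ATTENTION),
        ]
        stats = latency_stats(trials, simple_model)
        assert stats.t_on_sd == 0.0 and stats.n_on == 1

    def test_no_crossing_rejected(self, simple_model):
        trials = [
            make_trial([10.0] * 30, ATTENTION),  # never crosses upward
            make_trial([10.0] * 30, NON_ATTENTION),
        ]
        with pytest.raises(ValueError, match="no attention trial"):
            latency_stats(trials, simple_model)


class TestCountPulses:
    def test_all_below_threshold(self, simple_model):
        trial = make_trial([10.0] * 30, NON_ATTENTION)
        assert count_pulses(trial, simple_model, 2.0) == 0

    def test_run_length_oracle(self, simple_model):
        att = np.array(
            [70.0] * 3 + [10.0] * 2 + [70.0] * 5 + [10.0] * 2 + [70.0] * 7 + [10.0] * 11
        )
        trial = make_trial(att, NON_ATTENTION)
        # runs of 3, 5, 7 -> two runs >= 5
        assert count_pulses(trial, simple_model, 5.0) == 2
        assert count_pulses(trial, simple_model, 3.0) == 3
        assert count_pulses(trial, simple_model, 8.0) == 0

    def test_window_longer_than_trial(self, simple_model):
        trial = make_trial([70.0] * 30, NON_ATTENTION)
        assert count_pulses(trial, simple_model, 31.0) == 0

    def test_attention_trial_rejected(self, simple_model):
        with pytest.raises(ValueError, match="non-attention"):
            count_pulses(make_trial([70.0] * 30, ATTENTION), simple_model, 2.0)

    def test_non_increasing_in_t_w(self, simple_model, noisy_sessions):
        """Pulse count is exactly non-increasing in the dwell time."""
        for session in noisy_sessions:
            for trial in session.trials_of_type(NON_ATTENTION):
                counts = [
                    count_pulses(trial, simple_model, t_w) for t_w in range(2, 16)
                ]
                assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestConstraints:
    def test_tscan_reference_rows(self):
        # worked values from the published operating table
        assert np.isclose(tscan_min(LatencyStats(3.3, 2.0, 0, 0), 4.0), 10.58)
        assert np.isclose(tscan_min(LatencyStats(2.43, 0.8, 0, 0), 8.0), 11.742)

    def test_tscan_zero_latency_limit(self):
        assert tscan_min(LatencyStats(0.0, 0.0, 0.0, 0.0), 6.0) == 6.0

    def test_tscan_strictly_increasing(self):
        base = tscan_min(LatencyStats(2.0, 1.0, 0, 0), 4.0)
        assert tscan_min(LatencyStats(2.5, 1.0, 0, 0), 4.0) > base
        assert tscan_min(LatencyStats(2.0, 1.5, 0, 0), 4.0) > base
        assert tscan_min(LatencyStats(2.0, 1.0, 0, 0), 5.0) > base

    def test_feasible_vacuous_at_zero_pulses(self):
        stats = LatencyStats(2.0, 0.5, 1.0, 0.5)
        assert feasible(3.0, stats, 0.0, 4, t_scan=100.0)

    def test_boundary_equality_infeasible(self):
        stats = LatencyStats(2.0, 0.5, 1.0, 0.5)
        t_w = 1.0 + 1.64 * 0.5  # exactly the release bound
        assert not feasible(t_w, stats, 0.0, 4, t_scan=5.0)

    def test_pulse_constraint_strict(self):
        stats = LatencyStats(2.0, 0.0, 0.0, 0.0)
        # 1 * (4-1) * 10 = 30 < 30 is false
        assert not feasible(5.0, stats, 1.0, 4, t_scan=10.0)

    def test_icon_count_validated(self):
        with pytest.raises(ValueError, match="icons"):
            feasible(3.0, LatencyStats(0, 0, 0, 0), 0.0, 1, 5.0)


class TestFirstFeasibleWindow:
    def test_unconstrained_picks_grid_minimum(self):
        stats = LatencyStats(1.0, 0.0, 0.0, 0.0)
        rows = [(t_w, stats, 0.0) for t_w in range(2, 16)]
        assert first_feasible_window(rows, 4) == (2, 3.0)

    def test_release_bound_crossing_at_five(self):
        """Release bound 4.64 s makes t_w <= 4 infeasible, 5 feasible."""
        stats = LatencyStats(2.0, 0.5, 3.0, 1.0)  # bound = 3 + 1.64 = 4.64
        rows = [(t_w, stats, 0.0) for t_w in range(2, 16)]
        t_w_opt, _ = first_feasible_window(rows, 4)
        assert t_w_opt == 5

    def test_all_infeasible_returns_none(self):
        stats = LatencyStats(2.0, 0.5, 20.0, 5.0)  # bound = 28.2 > grid max
        rows = [(t_w, stats, 0.0) for t_w in range(2, 16)]
        assert first_feasible_window(rows, 4) is None


class TestSessionEvaluation:
    def test_ideal_subject_perfect_at_any_t_w(self, ideal_sessions):
        for t_w in (2.0, 8.0, 15.0):
            ev = session_evaluation(ideal_sessions[0], t_w, protocol=EvalProtocol(seed=5))
            assert ev.val_accuracy == 100.0
            assert ev.test_accuracy == 100.0

    def test_null_subject_near_chance(self):
        profile = SubjectProfile(
            "null", mu_att=50.0, mu_non=50.0, sigma_within=10.0,
            tau_on=0.0, tau_off=0.0, poor_signal_rate=0.0,
        )
        sessions = generate_cohort([profile], SimConfig(seed=3))["null"]
        accs = [
            session_evaluation(s, 2.0, protocol=EvalProtocol(seed=5)).test_accuracy
            for s in sessions
        ]
        mean_acc = np.mean(accs) / 100
        # 5 sessions x 10 repeats x 4 test trials = 200 predictions
        band = 1.96 * np.sqrt(0.25 / 200)
        assert abs(mean_acc - 0.5) <= band + 1e-9

    def test_determinism(self, noisy_sessions):
        a = session_evaluation(noisy_sessions[0], 4.0, protocol=EvalProtocol(seed=9))
        b = session_evaluation(noisy_sessions[0], 4.0, protocol=EvalProtocol(seed=9))
        assert a.val_accuracy == b.val_accuracy
        assert np.array_equal(a.t_on_values, b.t_on_values, equal_nan=True)

    def test_unbalanced_session_rejected(self, ideal_sessions):
        from attnaccess.core import Session

        short = Session(
            "ideal", 1, ideal_sessions[0].trials[:6]
        )
        with pytest.raises(ValueError, match="balanced"):
            session_evaluation(short, 2.0)


class TestOptimalWindow:
    def test_ideal_subject_grid_minimum(self, ideal_sessions):
        params = optimal_window(ideal_sessions, protocol=EvalProtocol(seed=5))
        assert params.t_w_opt == 2
        assert params.accuracy_pct == 100.0
        assert params.feasible
        # zero latency spread: t_scan = t_on_mean + t_w = 1 + 2
        assert np.isclose(params.t_scan, 3.0)
        assert np.isclose(params.itr_bits_per_min, 30.0)

    def test_result_satisfies_constraints_or_marker(self):
        profile = SubjectProfile(
            "weak", mu_att=55.0, mu_non=45.0, sigma_within=14.0,
            ar_coeff=0.7, tau_on=3.0, tau_off=3.0, poor_signal_rate=0.0,
        )
        sessions = generate_cohort([profile], SimConfig(seed=8))["weak"]
        params = optimal_window(sessions, protocol=EvalProtocol(seed=8))
        if params.feasible:
            assert feasible(
                params.t_w_opt, params.latency, params.np_at_opt,
                params.n_icons, params.t_scan,
            )
        else:
            assert params.t_w_opt is None and np.isnan(params.t_scan)


class TestItr:
    def test_perfect_binary_channel(self):
        assert itr(1.0, 2.0) == 30.0

    def test_chance_clamped_to_zero(self):
        with pytest.warns(UserWarning, match="chance"):
            assert itr(0.5, 2.0) == 0.0

    def test_binary_entropy_value(self):
        # 30 * (1 - H(0.9)) bits/min
        h = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))
        assert np.isclose(itr(0.9, 2.0), 30.0 * (1.0 - h))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            itr(0.0, 2.0)
        with pytest.raises(ValueError):
            itr(0.9, 0.0)
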