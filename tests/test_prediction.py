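"""Alarm rule, prediction time, metric identities, and both CV protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitensor.config import ConfigurationError
from epitensor.prediction import (
    EvaluationMetrics,
    alarm_scan,
    leave_one_segment_out,
    prediction_time,
    tenfold_cv,
)


def run_oracle(stream, alarm_len):
    """Naive oracle: first index ending a run of >= alarm_len consecutive 2s."""
    run = 0
    for i, lab in enumerate(stream):
        run = run + 1 if lab == 2 else 0
        if run >= alarm_len:
            return i
    return None


class TestAlarmScan:
    def test_29_twos_then_one_no_alert(self):
        stream = [2] * 29 + [1]
        assert not alarm_scan(stream, alarm_len=30).alert

    def test_30_twos_triggers_at_index_29(self):
        res = alarm_scan([2] * 30 + [1] * 5, alarm_len=30)
        assert res.alert and res.trigger_index == 29

    def test_counter_resets_on_interictal(self):
        stream = [2] * 10 + [1] + [2] * 30
        res = alarm_scan(stream, alarm_len=30)
        assert res.trigger_index == 40

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            alarm_scan([1, 2, 3], alarm_len=2)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_run_oracle(self, seed):
        rng = np.random.default_rng(seed)
        stream = rng.choice([1, 2], size=rng.integers(1, 120), p=[0.3, 0.7])
        alarm_len = int(rng.integers(1, 12))
        res = alarm_scan(stream, alarm_len=alarm_len)
        expected = run_oracle(stream, alarm_len)
        assert res.trigger_index == expected
        assert res.alert == (expected is not None)


class TestPredictionTime:
    def test_alert_at_final_window(self):
        assert prediction_time(50, 49, s=4.0) == 4.0

    def test_stated_arithmetic(self):
        # 674 windows, trigger at 500 -> n = 173 remaining, T = 4 * 174
        assert prediction_time(674, 500, s=4.0) == 696.0

    def test_linear_in_step(self):
        assert prediction_time(100, 40, s=8.0) == 2 * prediction_time(100, 40, s=4.0)

    def test_out_of_range_trigger(self):
        with pytest.raises(ValueError):
            prediction_time(10, 10)


class TestMetricIdentities:
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_identities_hold(self, tp, fp, tn, fn):
        m = EvaluationMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
        total = tp + fp + tn + fn
        if total:
            assert m.accuracy == pytest.approx((tp + tn) / total)
        if 2 * tp + fp + fn:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))


class TestTenfoldCv:
    def test_separable_features_perfect_metrics(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(8, 1, (50, 4))])
        y = np.array([1] * 50 + [2] * 50)
        m = tenfold_cv(X, y, M=50, E_grid=[2.0**-4, 1.0], seed=0)
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for rep in range(20):
            X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(4, 1, (30, 4))])
            y = rng.permutation([1] * 30 + [2] * 30)  # labels detached from X
            m = tenfold_cv(X, y, M=30, E_grid=[1.0], seed=rep)
            accs.append(m.accuracy)
        # mean of 20 runs x 60 rows: binomial 95% band around 0.5
        half_width = 1.96 * np.sqrt(0.25 / (20 * 60))
        assert abs(np.mean(accs) - 0.5) < half_width + 0.05

    def test_pooled_counts_match_identities(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1, 1, (30, 3))])
        y = np.array([1] * 30 + [2] * 30)
        m = tenfold_cv(X, y, M=20, E_grid=[1.0], seed=3)
        assert m.total == 60
        assert m.accuracy == (m.tp + m.tn) / 60

    def test_insufficient_samples_rejected(self):
        X = np.zeros((8, 2))
        y = np.array([1, 2] * 4)
        with pytest.raises(ConfigurationError):
            tenfold_cv(X, y, M=5, E_grid=[1.0], seed=0)

    def test_grouped_folds_keep_segments_intact(self):
        # rows of one group carry its id; any split mixing groups would let
        # the classifier memorize them, so grouped CV must not be perfect
        # when group identity is the only structure
        rng = np.random.default_rng(4)
        n_groups, rows = 12, 20
        X = np.vstack(
            [rng.normal(g, 0.01, (rows, 3)) for g in range(n_groups)]
        )
        y = np.repeat([1, 2] * (n_groups // 2), rows)
        groups = np.repeat(np.arange(n_groups), rows)
        m = tenfold_cv(X, y, M=30, E_grid=[1.0], seed=5, groups=groups, n_splits=6)
        assert m.accuracy < 0.9  # group labels are arbitrary -> no generalization


class TestLeaveOneSegmentOut:
    def _features(self, rng, labels, rows=40):
        return [rng.normal(lab * 6.0, 1.0, (rows, 3)) for lab in labels]

    @pytest.mark.parametrize(
        "constant,expected_sens,expected_spec",
        [(1, 0.0, 1.0), (2, 1.0, 0.0)],
    )
    def test_constant_classifier_degenerate_streams(
        self, monkeypatch, constant, expected_sens, expected_spec
    ):
        from epitensor import prediction as pred_mod

        monkeypatch.setattr(
            pred_mod.elm,
            "predict",
            lambda model, X: np.full(len(X), constant),
        )
        rng = np.random.default_rng(0)
        labels = [1, 1, 2, 2]
        feats = self._features(rng, labels)
        m, _ = leave_one_segment_out(
            feats, labels, M=10, E_grid=[1.0], alarm_len=5, seed=0
        )
        assert m.sensitivity == expected_sens
        assert m.specificity == expected_spec
        if constant == 1:
            assert m.mean_prediction_time_s is None

    def test_separated_segments_all_correct(self):
        rng = np.random.default_rng(5)
        labels = [1, 1, 1, 2, 2, 2]
        feats = self._features(rng, labels)
        m, traces = leave_one_segment_out(
            feats, labels, M=30, E_grid=[1.0], alarm_len=5, step_seconds=12.0, seed=1
        )
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        # alarm at index 4 of a 40-row stream: n = 35, T = 12 * 36
        assert m.mean_prediction_time_s == pytest.approx(12.0 * 36)

    def test_single_class_training_fold_skipped(self):
        rng = np.random.default_rng(6)
        labels = [1, 2]  # each fold's training set is single-class
        feats = self._features(rng, labels)
        m, traces = leave_one_segment_out(
            feats, labels, M=5, E_grid=[1.0], alarm_len=3, seed=0
        )
        assert m.total == 0 and traces == []
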