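"""Metrics against independent brute-force oracles, plus report aggregation."""

import numpy as np
import pandas as pd
import pytest

from dreamon import (
    RaterMatrix,
    aggregate_report,
    balanced_accuracy,
    build_rater_protocol,
    chance_threshold,
    delta_stability,
    expected_calibration_error,
    fleiss_kappa,
)
from dreamon.evaluate import RobustnessReport, interpret_kappa

from oracles import (
    balanced_accuracy_bruteforce,
    binomial_quantile_threshold_bruteforce,
    ece_bruteforce,
    fleiss_kappa_bruteforce,
)

rng = np.random.default_rng(2024)


def _random_probs(n, k):
    p = rng.random((n, k))
    return p / p.sum(axis=1, keepdims=True)


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        assert balanced_accuracy([0, 1, 2, 1], probs) == 1.0

    def test_hand_computed_recalls(self):
        # per-class recalls (1.0, 0.5, 0.0) -> mean 0.5
        y = [0, 1, 1, 2]
        pred = [0, 1, 0, 0]
        probs = np.eye(3)[pred]
        assert balanced_accuracy(y, probs) == pytest.approx(0.5)

    def test_equals_plain_accuracy_on_balanced_set(self):
        y = np.repeat([0, 1, 2], 10)
        probs = _random_probs(30, 3)
        plain = np.mean(probs.argmax(axis=1) == y)
        assert balanced_accuracy(y, probs) == pytest.approx(plain)

    def test_matches_bruteforce_on_random_instances(self):
        for _ in range(120):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(2, 21))
            y = rng.integers(k, size=n)
            probs = _random_probs(n, k)
            assert balanced_accuracy(y, probs) == pytest.approx(
                balanced_accuracy_bruteforce(y.tolist(), probs.argmax(axis=1).tolist())
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], np.zeros((0, 3)))


class TestECE:
    def test_confident_and_correct_is_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert expected_calibration_error(probs, [0, 1, 2]) == 0.0

    def test_single_bin_hand_computation(self):
        # 10 rows, confidence 0.8 each, 6 correct -> |0.6 - 0.8| = 0.2
        probs = np.tile([0.8, 0.1, 0.1], (10, 1))
        y = [0] * 6 + [1] * 4
        assert expected_calibration_error(probs, y) == pytest.approx(0.2)

    def test_permutation_invariance(self):
        probs = _random_probs(40, 3)
        y = rng.integers(3, size=40)
        perm = rng.permutation(40)
        assert expected_calibration_error(probs, y) == pytest.approx(
            expected_calibration_error(probs[perm], y[perm])
        )

    def test_matches_bruteforce_on_random_instances(self):
        for _ in range(120):
            n = int(rng.integers(1, 40))
            probs = _random_probs(n, 3)
            y = rng.integers(3, size=n)
            assert expected_calibration_error(probs, y) == pytest.approx(
                ece_bruteforce(probs, y.tolist())
            )

    def test_zero_when_binwise_calibrated(self):
        # all confidences identical and accuracy equal to that confidence
        probs = np.tile([0.75, 0.25, 0.0], (4, 1))
        y = [0, 0, 0, 1]  # 3/4 correct = 0.75 = confidence
        assert expected_calibration_error(probs, y) == pytest.approx(0.0)


class TestDelta:
    def test_hand_value(self):
        assert delta_stability([0.8, 0.6, 0.5]) == pytest.approx(0.3)

    def test_constant_and_order_invariance(self):
        assert delta_stability([0.4, 0.4, 0.4]) == 0.0
        m = rng.random(7)
        assert delta_stability(m) == delta_stability(m[::-1])
        with pytest.raises(ValueError):
            delta_stability([])


class TestChanceThreshold:
    def test_reference_value_90_trials(self):
        assert chance_threshold(90, 1 / 3, 0.05) == pytest.approx(37 / 90)

    def test_single_trial(self):
        assert chance_threshold(1, 1 / 3, 0.05) == 1.0

    def test_converges_to_chance(self):
        assert chance_threshold(100_000, 1 / 3, 0.05) - 1 / 3 < 0.01

    def test_matches_enumeration_oracle(self):
        for _ in range(120):
            n = int(rng.integers(1, 201))
            p = float(rng.uniform(0.05, 0.95))
            alpha = float(rng.uniform(0.01, 0.2))
            assert chance_threshold(n, p, alpha) == pytest.approx(
                binomial_quantile_threshold_bruteforce(n, p, alpha)
            )

    def test_invalid_parameters(self):
        for bad in [(0, 0.5, 0.05), (10, 0.0, 0.05), (10, 0.5, 1.5)]:
            with pytest.raises(ValueError):
                chance_threshold(*bad)


class TestFleissKappa:
    def test_perfect_agreement(self):
        m = np.array([[4, 0, 0], [0, 4, 0], [4, 0, 0]])
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_degenerate_single_category(self):
        assert fleiss_kappa(np.array([[4, 0], [4, 0]])) == 1.0

    def test_hand_evaluated_matrix(self):
        m = np.array([[3, 1, 0], [2, 2, 0], [4, 0, 0], [2, 1, 1]])
        assert fleiss_kappa(m) == pytest.approx(fleiss_kappa_bruteforce(m))

    def test_matches_textbook_oracle_on_random_matrices(self):
        for _ in range(120):
            n_items = int(rng.integers(2, 15))
            n_cat = int(rng.integers(2, 5))
            n_raters = int(rng.integers(2, 8))
            counts = rng.multinomial(n_raters, np.ones(n_cat) / n_cat, size=n_items)
            assert fleiss_kappa(counts) == pytest.approx(
                fleiss_kappa_bruteforce(counts), abs=1e-10
            )

    def test_random_ratings_give_near_zero_kappa(self):
        counts = rng.multinomial(4, [1 / 3] * 3, size=3000)
        assert abs(fleiss_kappa(counts)) < 0.03  # ~3 SEs of the null at this size

    def test_validation(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[2, 1], [3, 1]]))  # unequal row sums
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[1, 0], [0, 1]]))  # single rater
        with pytest.raises(ValueError):
            RaterMatrix(np.array([[2.5, 1.5]]))  # non-integer counts

    def test_interpretation_bands(self):
        assert interpret_kappa(0.5) == "moderate"
        assert interpret_kappa(0.7) == "substantial"
        assert interpret_kappa(-0.2) == "poor"


class TestRaterProtocol:
    @pytest.mark.parametrize(
        "n_raters, per_level, levels, expected",
        [(4, 30, range(7), 840), (1, 30, range(7), 210), (1, 1, [0], 1)],
    )
    def test_trial_counts(self, n_raters, per_level, levels, expected):
        roster = build_rater_protocol(n_raters, per_level, levels)
        assert len(roster) == expected

    def test_roster_structure(self):
        roster = build_rater_protocol(2, 3, [0, 5])
        assert set(roster.columns) >= {"rater_id", "item_id", "level", "response"}
        # every rater sees the same stimulus list
        lists = roster.groupby("rater_id")["item_id"].apply(tuple).unique()
        assert len(lists) == 1
        with pytest.raises(ValueError):
            build_rater_protocol(0, 30, [0])


class TestAggregation:
    def _cells(self):
        rows = []
        for run, acc in enumerate([0.3, 0.5, 0.4, 0.6, 0.5]):
            rows.append(
                dict(strategy="vanilla", run=run, family="gaussian", level=0,
                     balanced_accuracy=acc, ece=0.1)
            )
            rows.append(
                dict(strategy="vanilla", run=run, family="gaussian", level=1,
                     balanced_accuracy=acc - 0.1, ece=0.2)
            )
        return rows

    def test_median_is_middle_order_statistic(self):
        report = aggregate_report(self._cells(), n_test=90)
        lvl0 = report.aggregates[report.aggregates.level == 0]
        assert lvl0["median_balanced_accuracy"].iloc[0] == pytest.approx(0.5)

    def test_above_chance_flag_uses_threshold(self):
        report = aggregate_report(self._cells(), n_test=90)
        assert report.threshold == pytest.approx(37 / 90)
        flags = report.aggregates.set_index("level")["above_chance"]
        assert bool(flags.loc[0]) is True  # 0.5 > 0.411
        assert bool(flags.loc[1]) is False  # 0.4 < 0.411

    def test_single_run_median_is_value(self):
        cells = [dict(strategy="s", run=0, family="f", level=0, balanced_accuracy=0.42, ece=0.0)]
        report = aggregate_report(cells, n_test=90)
        assert report.aggregates["median_balanced_accuracy"].iloc[0] == pytest.approx(0.42)
        assert bool(report.aggregates["above_chance"].iloc[0]) is True

    def test_delta_per_strategy_family(self):
        report = aggregate_report(self._cells(), n_test=90)
        assert report.deltas["delta"].iloc[0] == pytest.approx(0.1)

    def test_report_round_trip(self, tmp_path):
        report = aggregate_report(self._cells(), n_test=90)
        report.save(tmp_path)
        loaded = RobustnessReport.load(tmp_path)
        pd.testing.assert_frame_equal(
            loaded.aggregates.reset_index(drop=True), report.aggregates.reset_index(drop=True)
        )
        assert loaded.n_test == report.n_test
        assert loaded.threshold == report.threshold
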