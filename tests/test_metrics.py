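"""Aggregation arithmetic on the published reference columns and hand tallies."""

import numpy as np
import pytest

from swarmbo import refdata
from swarmbo.metrics import (compare_table, compare_table_csv,
                             confusion_summary, mean_accuracy, summary_stats)


class TestMeanAccuracy:
    def test_mean_of_constants(self):
        assert mean_accuracy([20.55] * 11) == pytest.approx(20.55)

    def test_lcb_vgg16_column_mean(self):
        # direct summation of the printed per-iteration values
        mean = mean_accuracy(refdata.VGG16_ACCURACY["LCB"])
        assert mean == pytest.approx(47.1763, abs=1e-3)

    def test_per_class_rates_average_to_reported_overall(self):
        assert mean_accuracy(refdata.VGG16_PER_CLASS_RATES) == pytest.approx(
            97.83, abs=0.01)

    def test_agrees_with_fold_left_summation(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(15, 99, 137)
        total = 0.0
        for v in values:
            total += v
        assert mean_accuracy(values) == pytest.approx(total / len(values),
                                                      rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_accuracy([])


class TestSummaryStats:
    def test_ucb_vgg16_median(self):
        s = summary_stats(refdata.VGG16_ACCURACY["UCB"])
        assert s.median == pytest.approx(20.55)

    def test_ei_sfo_vgg16_extrema(self):
        s = summary_stats(refdata.VGG16_ACCURACY["EI-SFO"])
        assert s.max == pytest.approx(98.60)
        assert s.min == pytest.approx(16.65)

    def test_single_value_degenerates(self):
        s = summary_stats([42.0])
        assert (s.mean, s.max, s.min, s.median, s.q1, s.q3) == (42.0,) * 6

    def test_order_statistics_consistent(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 100, 51)
        s = summary_stats(values)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
        assert s.min <= s.mean <= s.max

    def test_permutation_invariant(self):
        values = refdata.VGG16_ACCURACY["LCB"]
        assert summary_stats(values) == summary_stats(values[::-1])


class TestConfusionSummary:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        s = confusion_summary(y, y, classes=("a", "b", "c"))
        assert np.all(s.per_class_rate == 100.0)
        assert s.overall == 100.0

    def test_reported_vgg19_overall_from_per_class_rates(self):
        # rebuild label vectors whose per-class rates are the published ones
        y_true, y_pred = [], []
        classes = ("central", "superior", "hemianopia", "quadrantanopia",
                   "normal", "tunnel")
        for cls, rate in zip(classes, refdata.VGG19_PER_CLASS_RATES):
            other = classes[0] if cls != classes[0] else classes[1]
            y_true += [cls] * 100
            y_pred += [cls] * rate + [other] * (100 - rate)
        s = confusion_summary(y_true, y_pred, classes)
        assert s.overall == pytest.approx(98.33, abs=0.01)

    def test_two_class_hand_tally(self):
        y_true = ["x"] * 4 + ["y"] * 4
        y_pred = ["x", "x", "x", "y", "y", "y", "y", "y"]
        s = confusion_summary(y_true, y_pred, classes=("x", "y"))
        np.testing.assert_array_equal(s.counts, [[3, 1], [0, 4]])
        np.testing.assert_allclose(s.per_class_rate, [75.0, 100.0])
        assert s.overall == pytest.approx(87.5)

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(2)
        classes = tuple("abcdef")
        y_true = rng.choice(classes, 200).tolist()
        y_pred = rng.choice(classes, 200).tolist()
        s = confusion_summary(y_true, y_pred, classes)
        assert s.counts.sum() == 200

    def test_zero_support_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero support"):
            s = confusion_summary(["a", "a"], ["a", "b"], classes=("a", "b", "c"))
        assert np.isnan(s.per_class_rate[1]) and np.isnan(s.per_class_rate[2])
        assert s.overall == pytest.approx(50.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary(["a"], ["a", "b"], classes=("a", "b"))


class TestCompareTable:
    def test_reference_columns_reproduce_reported_extrema(self):
        rows = compare_table({
            "EI/VGG-16": [refdata.VGG16_ACCURACY["EI"]],
            "EI/VGG-19": [refdata.VGG19_ACCURACY["EI"]],
        })
        by_variant = {r["variant"]: r for r in rows}
        assert by_variant["EI/VGG-16"]["max"] == pytest.approx(97.92)
        assert by_variant["EI/VGG-16"]["min"] == pytest.approx(18.81)
        assert by_variant["EI/VGG-19"]["max"] == pytest.approx(20.55)
        assert by_variant["EI/VGG-19"]["min"] == pytest.approx(17.37)

    def test_identical_runs_under_two_names_give_identical_rows(self):
        values = refdata.VGG16_ACCURACY["PI"]
        rows = compare_table({"A": [values], "B": [values]})
        a = {k: v for k, v in rows[0].items() if k != "variant"}
        b = {k: v for k, v in rows[1].items() if k != "variant"}
        assert a == b

    def test_multi_run_pooled_row_and_csv(self):
        rows = compare_table({"EI": [[10.0, 20.0], [30.0, 40.0]]})
        assert [r["run"] for r in rows] == ["1", "2", "all-runs"]
        assert rows[-1]["mean"] == pytest.approx(25.0)
        csv_text = compare_table_csv(rows)
        assert csv_text.splitlines()[0].startswith("Acquisition Function,")
        assert len(csv_text.splitlines()) == 4

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_table({})
        with pytest.raises(ValueError):
            compare_table({"EI": []})
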