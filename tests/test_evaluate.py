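"""Evaluation surfaces and two-logger comparison statistics, including the
published accuracy-difference arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from collaraccel.evaluate import (compare_devices, confusion_matrix,
                                  mean_difference, misclassification_shares,
                                  overall_accuracy, per_class_accuracy,
                                  percent_difference)
from collaraccel.studydata import CATEGORISATION_ACCURACY


def chi2_2x2_oracle(a, b, c, d):
    """Closed-form Pearson chi-square for a 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "a", "c"]
        cm = confusion_matrix(y, y)
        assert (cm.to_numpy() == np.diag(np.diag(cm.to_numpy()))).all()

    def test_direct_tally(self):
        truth = ["A"] * 4 + ["B"] * 2
        pred = ["A", "A", "A", "B", "B", "B"]
        cm = confusion_matrix(truth, pred)
        assert cm.loc["A", "A"] == 3 and cm.loc["A", "B"] == 1
        assert cm.loc["B", "A"] == 0 and cm.loc["B", "B"] == 2

    def test_matches_double_loop_oracle(self, rng):
        labels = ["w", "x", "y", "z"]
        truth = rng.choice(labels, 500)
        pred = rng.choice(labels, 500)
        cm = confusion_matrix(truth, pred, labels=labels)
        for t in labels:
            for p in labels:
                expect = sum(1 for a, b in zip(truth, pred)
                             if a == t and b == p)
                assert cm.loc[t, p] == expect

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["a", "b"])


class TestPerClassAccuracy:
    def test_diagonal_matrix_is_hundred_percent(self):
        cm = pd.DataFrame([[5, 0], [0, 3]], index=["a", "b"],
                          columns=["a", "b"])
        assert per_class_accuracy(cm) == {"a": 100.0, "b": 100.0}

    def test_arithmetic_example(self):
        cm = pd.DataFrame([[3, 1], [0, 2]], index=["A", "B"],
                          columns=["A", "B"])
        acc = per_class_accuracy(cm)
        assert acc["A"] == pytest.approx(75.0)
        assert acc["B"] == pytest.approx(100.0)

    def test_zero_support_class_absent(self):
        cm = pd.DataFrame([[2, 0], [0, 0]], index=["a", "b"],
                          columns=["a", "b"])
        assert "b" not in per_class_accuracy(cm)

    def test_support_weighted_recalls_reproduce_overall(self, rng):
        labels = ["a", "b", "c"]
        cm = pd.DataFrame(rng.integers(1, 30, (3, 3)), index=labels,
                          columns=labels)
        acc = per_class_accuracy(cm)
        support = cm.sum(axis=1)
        weighted = sum(acc[l] * support[l] for l in labels) / support.sum()
        assert weighted == pytest.approx(overall_accuracy(cm, set()))


class TestOverallAccuracy:
    def test_diagonal_matrix_any_disregard(self):
        cm = pd.DataFrame(np.diag([4, 5, 6]), index=list("abc"),
                          columns=list("abc"))
        assert overall_accuracy(cm, set()) == 100.0
        assert overall_accuracy(cm, {"a"}) == 100.0

    def test_disregarding_ragbag_errors_raises_accuracy(self):
        # errors confined to "other" rows: disregarded accuracy is perfect
        cm = pd.DataFrame([[10, 0, 0], [0, 10, 0], [3, 4, 3]],
                          index=["lie", "walk", "other"],
                          columns=["lie", "walk", "other"])
        plain = overall_accuracy(cm, set())
        disregarded = overall_accuracy(cm, {"other"})
        assert disregarded == 100.0 > plain

    def test_matches_row_filtered_trace_oracle(self, rng):
        labels = ["a", "b", "other"]
        cm = pd.DataFrame(rng.integers(0, 40, (3, 3)) + 1, index=labels,
                          columns=labels)
        keep = ["a", "b"]
        oracle = 100.0 * sum(cm.loc[l, l] for l in keep) \
            / cm.loc[keep].to_numpy().sum()
        assert overall_accuracy(cm, {"other"}) == pytest.approx(oracle)

    def test_disregarding_all_error_rows_gives_hundred(self, rng):
        labels = list("abcd")
        m = np.diag(rng.integers(5, 20, 4))
        m[2, 0] = 3  # only row "c" has errors
        cm = pd.DataFrame(m, index=labels, columns=labels)
        assert overall_accuracy(cm, {"c"}) == 100.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy(pd.DataFrame())


class TestMisclassificationShares:
    def _cm(self):
        return pd.DataFrame([[2, 6, 2], [0, 5, 0], [1, 0, 9]],
                            index=list("ABC"), columns=list("ABC"))

    def test_all_correct_row_gives_empty_table(self):
        cm = pd.DataFrame([[10, 0, 0], [0, 1, 0], [0, 0, 1]],
                          index=list("ABC"), columns=list("ABC"))
        assert misclassification_shares(cm, "A") == {}

    def test_row_total_denominator(self):
        shares = misclassification_shares(self._cm(), "A")
        assert shares == {"B": pytest.approx(60.0),
                          "C": pytest.approx(20.0)}

    def test_error_denominator_flag(self):
        shares = misclassification_shares(self._cm(), "A", of_errors=True)
        assert shares == {"B": pytest.approx(75.0),
                          "C": pytest.approx(25.0)}

    def test_matches_division_oracle(self, rng):
        labels = list("abcd")
        cm = pd.DataFrame(rng.integers(1, 30, (4, 4)), index=labels,
                          columns=labels)
        for beh in labels:
            shares = misclassification_shares(cm, beh)
            row = cm.loc[beh]
            for lab, pct in shares.items():
                assert pct == pytest.approx(100.0 * row[lab] / row.sum())


class TestCompareDevices:
    def test_identical_proportions_null_case(self):
        row = compare_devices("walk", 30, 100, 30, 100)
        assert row.chi2 == pytest.approx(0.0, abs=1e-12)
        assert row.verdict == "n.d."
        assert row.percent_difference == 0.0

    def test_chi2_matches_closed_form(self):
        row = compare_devices("walk", 30, 100, 50, 100)
        oracle = chi2_2x2_oracle(30, 70, 50, 50)
        assert row.chi2 == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(8.33, abs=0.01)
        assert row.df == 1

    def test_small_expected_count_takes_fisher_branch(self):
        row = compare_devices("sitting stalk", 23, 24, 41, 41)
        assert row.chi2 is None and row.odds_ratio is not None
        # Fisher oracle straight from scipy on the same table
        or_, p = stats.fisher_exact([[23, 1], [41, 0]])
        assert row.p == pytest.approx(p)

    def test_fisher_odds_ratio_is_one_when_ad_equals_bc(self):
        row = compare_devices("x", 2, 4, 3, 6, small_count_threshold=10)
        assert row.odds_ratio == pytest.approx(1.0)

    def test_verdict_goes_to_better_device_when_significant(self):
        row = compare_devices("trot", 200, 1000, 500, 1000)
        assert row.p < 0.05 and row.verdict == "GCDC"
        swapped = compare_devices("trot", 500, 1000, 200, 1000)
        assert swapped.verdict == "CEFAS"

    def test_antisymmetry_under_device_swap(self, rng):
        for _ in range(20):
            ca, na = int(rng.integers(10, 90)), 100
            cb, nb = int(rng.integers(10, 90)), 120
            ab = compare_devices("b", ca, na, cb, nb)
            ba = compare_devices("b", cb, nb, ca, na)
            assert ab.percent_difference == pytest.approx(
                -ba.percent_difference)
            if ab.chi2 is not None:
                assert ab.chi2 == pytest.approx(ba.chi2)

    def test_chi2_zero_iff_equal_proportions(self):
        equal = compare_devices("b", 40, 80, 60, 120)
        assert equal.chi2 == pytest.approx(0.0, abs=1e-12)
        unequal = compare_devices("b", 40, 80, 70, 120)
        assert unequal.chi2 > 0

    def test_zero_device_margin_rejected(self):
        with pytest.raises(ValueError):
            compare_devices("b", 0, 0, 5, 10)


class TestPublishedDifferences:
    """Accuracy differences recompute from the published per-behaviour
    accuracies at printed precision."""

    fine = CATEGORISATION_ACCURACY["fine"]
    medium = CATEGORISATION_ACCURACY["medium"]
    coarse = CATEGORISATION_ACCURACY["coarse"]

    @pytest.mark.parametrize("behaviour,expected", [
        ("stand", +2.6), ("trot", -16.1), ("pounce", -51.2),
        ("crouch", -13.7), ("gallop", +8.8),
    ])
    def test_fine_percent_differences(self, behaviour, expected):
        diff = percent_difference(self.fine["CEFAS"][behaviour],
                                  self.fine["GCDC"][behaviour])
        assert diff == pytest.approx(expected, abs=0.05)

    def test_fine_mean_difference(self):
        diffs = [self.fine["CEFAS"][b] - self.fine["GCDC"][b]
                 for b in self.fine["CEFAS"]]
        assert len(diffs) == 16
        assert mean_difference(diffs) == pytest.approx(-6.4, abs=0.05)

    def test_medium_mean_difference(self):
        diffs = [self.medium["CEFAS"][b] - self.medium["GCDC"][b]
                 for b in self.medium["CEFAS"]]
        assert len(diffs) == 11
        assert mean_difference(diffs) == pytest.approx(-3.3, abs=0.05)

    def test_coarse_mean_difference(self):
        diffs = [self.coarse["CEFAS"][b] - self.coarse["GCDC"][b]
                 for b in self.coarse["CEFAS"]]
        assert len(diffs) == 3
        assert mean_difference(diffs) == pytest.approx(-4.0, abs=0.05)

    def test_single_row_mean_is_itself(self):
        assert mean_difference([-2.5]) == -2.5

    def test_empty_mean_rejected(self):
        with pytest.raises(ValueError):
            mean_difference([])
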