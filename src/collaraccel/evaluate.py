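"""Evaluation surfaces: confusion matrices, per-behaviour accuracy,
rag-bag-disregarded overall accuracy, misclassification shares, and the
two-logger comparison statistics.

"Categorisation accuracy" for a behaviour is per-class recall (diagonal /
row sum of the confusion matrix) — the only reading consistent with
row-normalised confusion reporting. Logger comparison builds, per
behaviour, a 2x2 table (device x correct/incorrect) tested by Pearson χ²
(df = 1, no continuity correction), falling back to Fisher's exact test
(odds ratio reported in lieu of χ²) when any expected count is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion


def confusion_matrix(truth, predicted, labels: list[str] | None = None
                     ) -> pd.DataFrame:
    """Exact cross-tabulation; rows = true label, columns = predicted."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(truth) != len(predicted):
        raise ValueError("truth/prediction length mismatch")
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    m = _sk_confusion(truth, predicted, labels=labels)
    return pd.DataFrame(m, index=labels, columns=labels)


def per_class_accuracy(cm: pd.DataFrame) -> dict[str, float]:
    """Per-behaviour categorisation accuracy (recall), %.

    Classes with zero support (empty rows) are omitted.
    """
    out = {}
    for lab in cm.index:
        support = cm.loc[lab].sum()
        if support > 0:
            out[str(lab)] = 100.0 * cm.loc[lab, lab] / support
    return out


def overall_accuracy(cm: pd.DataFrame,
                     disregard: set[str] = frozenset({"other"})) -> float:
    """Overall accuracy, %, optionally disregarding rag-bag true rows.

    Rows whose TRUE label is in ``disregard`` are excluded from numerator
    and denominator; their columns stay (predictions into a disregarded
    class still count against the classifier).
    """
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    keep = [lab for lab in cm.index if lab not in disregard]
    sub = cm.loc[keep]
    total = sub.to_numpy().sum()
    if total == 0:
        raise ValueError("no rows remain after disregarding")
    correct = sum(sub.loc[lab, lab] for lab in keep if lab in sub.columns)
    return 100.0 * correct / total


def misclassification_shares(cm: pd.DataFrame, behaviour: str,
                             of_errors: bool = False) -> dict[str, float]:
    """Where a behaviour's events go when misclassified, %.

    By default shares are of the behaviour's total events (row total); with
    ``of_errors`` they are of its misclassified events only. Returns an
    empty table when every event is correct.
    """
    row = cm.loc[behaviour]
    total = row.sum()
    errors = total - row[behaviour]
    if errors == 0:
        return {}
    denom = errors if of_errors else total
    return {str(lab): 100.0 * row[lab] / denom
            for lab in cm.columns if lab != behaviour and row[lab] > 0}


@dataclass(frozen=True)
class DeviceComparisonRow:
    """Per-behaviour two-logger accuracy comparison.

    percent_difference is accuracy_a − accuracy_b in percentage points;
    the test is Pearson χ² on the 2x2 device-by-outcome table, or Fisher's
    exact test (odds_ratio reported, chi2/df None) when any expected count
    falls below the small-count threshold. verdict names the significantly
    better device at p < 0.05, else "n.d.".
    """

    behaviour: str
    accuracy_a: float
    accuracy_b: float
    percent_difference: float
    chi2: float | None
    df: int | None
    p: float
    odds_ratio: float | None
    verdict: str


def compare_devices(behaviour: str, correct_a: int, n_a: int,
                    correct_b: int, n_b: int,
                    small_count_threshold: float = 5.0,
                    device_a: str = "CEFAS",
                    device_b: str = "GCDC") -> DeviceComparisonRow:
    """Compare two loggers' categorisation of one behaviour."""
    if n_a < 1 or n_b < 1:
        raise ValueError("each device needs at least one event")
    table = np.array([[correct_a, n_a - correct_a],
                      [correct_b, n_b - correct_b]], dtype=float)
    if np.any(table < 0):
        raise ValueError("correct counts exceed totals")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table (zero device margin)")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    acc_a = 100.0 * correct_a / n_a
    acc_b = 100.0 * correct_b / n_b
    # a zero outcome margin (e.g. both devices perfect) has expected
    # counts of 0 and therefore always takes the exact-test branch
    if np.any(expected < small_count_threshold):
        odds_ratio, p = stats.fisher_exact(table.astype(int))
        chi2 = df = None
    else:
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        chi2 = float(chi2)
        df = int(df)
        odds_ratio = None
    if p < 0.05:
        verdict = device_a if acc_a > acc_b else device_b
    else:
        verdict = "n.d."
    return DeviceComparisonRow(
        behaviour=behaviour, accuracy_a=acc_a, accuracy_b=acc_b,
        percent_difference=acc_a - acc_b, chi2=chi2, df=df, p=float(p),
        odds_ratio=None if odds_ratio is None else float(odds_ratio),
        verdict=verdict)


def percent_difference(accuracy_a: float, accuracy_b: float) -> float:
    """Accuracy difference in percentage points (a − b)."""
    return accuracy_a - accuracy_b


def mean_difference(rows) -> float:
    """Mean percent difference over behaviours, excluding "other".

    Accepts DeviceComparisonRow objects or bare percent differences.
    """
    diffs = []
    for r in rows:
        if isinstance(r, DeviceComparisonRow):
            if r.behaviour == "other":
                continue
            diffs.append(r.percent_difference)
        else:
            diffs.append(float(r))
    if not diffs:
        raise ValueError("no behaviours to average")
    return float(np.mean(diffs))


def comparison_table(rows: list[DeviceComparisonRow]) -> pd.DataFrame:
    """Flat table of per-behaviour comparisons (one row per behaviour)."""
    return pd.DataFrame([{
        "behaviour": r.behaviour,
        "accuracy_a": r.accuracy_a,
        "accuracy_b": r.accuracy_b,
        "percent_difference": r.percent_difference,
        "statistic": r.chi2 if r.chi2 is not None else r.odds_ratio,
        "test": "chi2" if r.chi2 is not None else "fisher",
        "df": r.df,
        "p": r.p,
        "verdict": r.verdict,
    } for r in rows])
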