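"""Random-forest behaviour models: split, early-stopped fit, depth tuning,
cross-validation, and variable importance.

Protocol: each labelled logging event (one accelerometer sample with its 14
predictor channels) is one case. Cases are split 60/20/20 into train /
validation / test at random; the forest is grown incrementally and stops
early once the two-tree moving average of validation accuracy no longer
improves by 0.1 percentage points over the previous two-tree average; depth
is refined over a small grid by validation accuracy; 5-fold cross-validation
checks for overfitting. Test metrics are computed exactly once.

Metric conventions (chosen so outputs are comparable in form with the
reporting style of tree-ensemble frameworks used in biologging studies):
MSE is the mean of (1 − p(true class))² over cases, RMSE its square root,
and r² = 1 − MSE / Var(numeric class codes) of the evaluated responses.
Class imbalance is left uncorrected, and rag-bag "other" rows stay in
training and prediction; they are only disregarded at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from .features import FEATURE_COLUMNS

PREDICTORS = list(FEATURE_COLUMNS)
LABEL_COLUMN = "behaviour"


@dataclass(frozen=True)
class SplitSpec:
    """Random 60/20/20 train/validation/test row partition."""

    train_frac: float = 0.6
    valid_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.valid_frac + self.test_frac
        if not np.isclose(total, 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class ModelConfig:
    """Forest-fitting configuration.

    n_trees caps the forest; the early-stopping rule usually halts growth
    well below it. depth_grid lists candidate max depths for refinement.
    """

    n_trees: int = 500
    depth_grid: tuple[int | None, ...] = (5, 10, 20)
    stopping_rounds: int = 2
    stopping_tolerance: float = 0.001
    cv_folds: int = 5
    seed: int = 0
    eval_every: int = 2  # trees per stopping-rule evaluation block

    def __post_init__(self) -> None:
        if not self.depth_grid:
            raise ValueError("depth_grid must be non-empty")
        if not (0 < self.stopping_tolerance < 1):
            raise ValueError("stopping_tolerance must lie in (0, 1)")


@dataclass(frozen=True)
class FitMetrics:
    """Accuracy and probability-error metrics for one dataset."""

    accuracy: float
    mse: float
    rmse: float
    r2: float
    tag: str
    sd: dict[str, float] | None = None  # over CV folds, when tag == "cv-mean"


@dataclass
class FitResult:
    """A trained behaviour model with its evaluation artefacts."""

    model: RandomForestClassifier
    chosen_depth: int | None
    n_trees_used: int
    metrics: dict[str, FitMetrics]
    confusion_valid: pd.DataFrame
    importance: pd.DataFrame
    confusion_test: pd.DataFrame | None = None

    def evaluate_test(self, test: pd.DataFrame) -> FitMetrics:
        """Score the held-out test set; allowed exactly once."""
        if "test" in self.metrics:
            raise RuntimeError("test metrics already computed once")
        m = compute_metrics(self.model, test, tag="test")
        self.metrics["test"] = m
        self.confusion_test = _confusion(self.model, test)
        return m


def split_dataset(dataset: pd.DataFrame, spec: SplitSpec
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint seeded random row partition with 60/20/20 rounding.

    Train receives floor(train_frac·n) rows, validation floor(valid_frac·n),
    test the remainder.
    """
    n = len(dataset)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.train_frac * n))
    n_valid = int(np.floor(spec.valid_frac * n))
    idx_train = perm[:n_train]
    idx_valid = perm[n_train:n_train + n_valid]
    idx_test = perm[n_train + n_valid:]
    return (dataset.iloc[idx_train].reset_index(drop=True),
            dataset.iloc[idx_valid].reset_index(drop=True),
            dataset.iloc[idx_test].reset_index(drop=True))


def _xy(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in PREDICTORS if c not in dataset.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    return (dataset[PREDICTORS].to_numpy(float),
            dataset[LABEL_COLUMN].to_numpy(object))


def compute_metrics(model: RandomForestClassifier, dataset: pd.DataFrame,
                    tag: str) -> FitMetrics:
    """Accuracy, (R)MSE and r² of a fitted model on a dataset."""
    X, y = _xy(dataset)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    class_index = {c: i for i, c in enumerate(classes)}
    # probability assigned to the true class; 0 for unseen classes
    p_true = np.zeros(len(y))
    for i, lab in enumerate(y):
        j = class_index.get(lab)
        if j is not None:
            p_true[i] = proba[i, j]
    pred = model.predict(X)
    accuracy = float(np.mean(pred == y))
    mse = float(np.mean((1.0 - p_true) ** 2))
    codes = np.array([class_index.get(lab, len(classes)) for lab in y],
                     dtype=float)
    var = float(np.var(codes))
    r2 = float(1.0 - mse / var) if var > 0 else float("nan")
    return FitMetrics(accuracy=accuracy, mse=mse, rmse=float(np.sqrt(mse)),
                      r2=r2, tag=tag)


def _confusion(model: RandomForestClassifier,
               dataset: pd.DataFrame) -> pd.DataFrame:
    from .evaluate import confusion_matrix

    X, y = _xy(dataset)
    pred = model.predict(X)
    labels = sorted(set(y) | set(pred))
    return confusion_matrix(y, pred, labels=labels)


def train_rf(train: pd.DataFrame, valid: pd.DataFrame, config: ModelConfig,
             max_depth: int | None = None) -> FitResult:
    """Fit an early-stopped random forest.

    Trees are added ``eval_every`` at a time (warm start); after each block
    the validation overall accuracy is recorded, and growth stops when the
    ``stopping_rounds``-block moving average improves on the previous
    ``stopping_rounds``-block average by less than ``stopping_tolerance``.
    """
    _, y_train = _xy(train)
    if len(set(y_train)) < 2:
        raise ValueError("training data contain a single class")
    X_train = train[PREDICTORS].to_numpy(float)
    X_valid, y_valid = _xy(valid)

    model = RandomForestClassifier(
        n_estimators=0, warm_start=True, max_depth=max_depth,
        random_state=config.seed, n_jobs=1)
    history: list[float] = []
    k = config.stopping_rounds
    n_trees = 0
    while n_trees < config.n_trees:
        n_trees = min(n_trees + config.eval_every, config.n_trees)
        model.set_params(n_estimators=n_trees)
        model.fit(X_train, y_train)
        history.append(float(np.mean(model.predict(X_valid) == y_valid)))
        if len(history) >= 2 * k:
            current = float(np.mean(history[-k:]))
            previous = float(np.mean(history[-2 * k:-k]))
            if current - previous < config.stopping_tolerance:
                break

    metrics = {
        "train": compute_metrics(model, train, tag="train"),
        "valid": compute_metrics(model, valid, tag="valid"),
    }
    return FitResult(model=model, chosen_depth=max_depth,
                     n_trees_used=n_trees, metrics=metrics,
                     confusion_valid=_confusion(model, valid),
                     importance=variable_importance_from_model(model))


def tune_depth(train: pd.DataFrame, valid: pd.DataFrame,
               config: ModelConfig) -> FitResult:
    """Refine depth over the grid; retain the highest validation accuracy.

    Ties break to the smallest depth (None, an unlimited depth, sorts
    last).
    """
    def depth_key(d):
        return (d is None, d if d is not None else 0)

    best: FitResult | None = None
    for depth in sorted(config.depth_grid, key=depth_key):
        fit = train_rf(train, valid, config, max_depth=depth)
        if best is None or (fit.metrics["valid"].accuracy
                            > best.metrics["valid"].accuracy):
            best = fit
    assert best is not None
    return best


def cross_validate(dataset: pd.DataFrame, config: ModelConfig,
                   max_depth: int | None = None
                   ) -> tuple[list[FitMetrics], FitMetrics]:
    """Seeded k-fold cross-validation; per-fold metrics plus mean ± sd."""
    if config.cv_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(dataset) < config.cv_folds:
        raise ValueError("fewer rows than folds")
    kf = KFold(n_splits=config.cv_folds, shuffle=True,
               random_state=config.seed)
    fold_metrics: list[FitMetrics] = []
    X = dataset[PREDICTORS].to_numpy(float)
    y = dataset[LABEL_COLUMN].to_numpy(object)
    for i, (tr, te) in enumerate(kf.split(X)):
        model = RandomForestClassifier(
            n_estimators=min(config.n_trees, 100), max_depth=max_depth,
            random_state=config.seed, n_jobs=1)
        model.fit(X[tr], y[tr])
        fold_metrics.append(
            compute_metrics(model, dataset.iloc[te], tag=f"fold{i}"))
    fields = ("accuracy", "mse", "rmse", "r2")
    means = {f: float(np.mean([getattr(m, f) for m in fold_metrics]))
             for f in fields}
    sds = {f: float(np.std([getattr(m, f) for m in fold_metrics], ddof=1))
           for f in fields}
    summary = FitMetrics(accuracy=means["accuracy"], mse=means["mse"],
                         rmse=means["rmse"], r2=means["r2"],
                         tag="cv-mean", sd=sds)
    return fold_metrics, summary


def variable_importance_from_model(model: RandomForestClassifier
                                   ) -> pd.DataFrame:
    """Impurity importances with scaled and explanatory-power columns.

    scaled_importance = 100·raw/max(raw) (% of the best predictor);
    explanatory_power = 100·raw/sum(raw) (% of total improvement).
    """
    raw = np.asarray(model.feature_importances_, float)
    mx = raw.max() if raw.max() > 0 else 1.0
    total = raw.sum() if raw.sum() > 0 else 1.0
    df = pd.DataFrame({
        "predictor": PREDICTORS,
        "raw_importance": raw,
        "scaled_importance": 100.0 * raw / mx,
        "explanatory_power": 100.0 * raw / total,
    })
    return df.sort_values("raw_importance",
                          ascending=False).reset_index(drop=True)


def variable_importance(fit: FitResult) -> pd.DataFrame:
    """Importance table of a fit (see variable_importance_from_model)."""
    return variable_importance_from_model(fit.model)
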