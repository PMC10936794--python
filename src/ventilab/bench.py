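"""Classifier benchmark, confusion-matrix metrics and the rule network.

Six classifier families are benchmarked on breath tables: a Gini
decision tree (DT), a hyperparameter-optimized tree (OBT), Gaussian
naive Bayes (NBT), Euclidean k-nearest neighbours (NeNT), an AdaBoost
ensemble (ET) and a ReLU feed-forward network (NNT).  The families are
deliberately off-the-shelf scikit-learn estimators; the package's value
is the harness — stratified 70/30 evaluation, grid search inside seeded
5-fold cross-validation, confusion-matrix metrics, ROC — and its
reproducibility.

Metric conventions: the positive class is pressure-controlled mode
(label 1); accuracy is reported as a percentage to one decimal, the
remaining proportions to four decimals.  Training time is recorded but
informational only (hardware-dependent).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from ventilab.dataset import (
    LABEL_COLUMN,
    BreathTable,
    one_hot,
    split,
    zscore,
)
from ventilab.errors import (
    ConfigurationError,
    DegenerateROCError,
    DomainError,
    ParameterError,
    PlanError,
    SignalError,
)

FAMILIES = ("DT", "OBT", "NBT", "NeNT", "ET", "NNT")


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = pressure mode (label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in [("tp", self.tp), ("tn", self.tn), ("fp", self.fp), ("fn", self.fn)]:
            if v < 0 or v != int(v):
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same counts under the opposite positive-class convention."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count tp/tn/fp/fn over paired binary labels (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise SignalError(
            f"label length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if len(y_true) < 1:
        raise SignalError("need at least one labelled sample")
    for arr, name in [(y_true, "y_true"), (y_pred, "y_pred")]:
        if not set(np.unique(arr)) <= {0, 1}:
            raise SignalError(f"{name} must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class MetricsReport:
    """Confusion-matrix metric set, each in [0, 1] where defined.

    A metric whose denominator is zero is undefined: it is reported as
    NaN and its name is listed in ``undefined``.  F1 is zero by
    convention when precision and sensitivity are both zero.
    """

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    undefined: Tuple[str, ...] = ()
    training_time: float = float("nan")
    roc_points: Optional[np.ndarray] = None
    auc: float = float("nan")

    @property
    def accuracy_pct(self) -> float:
        """Accuracy as a percentage, rounded to one decimal."""
        return round(self.accuracy * 100.0, 1)

    def rounded(self) -> Dict[str, float]:
        """Printed-table conventions: accuracy % to 1 dp, others to 4 dp."""
        return {
            "accuracy_pct": self.accuracy_pct,
            "precision": round(self.precision, 4),
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "f1": round(self.f1, 3),
        }


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and F1 from counts.

    accuracy    = (tp + tn) / total
    precision   = tp / (tp + fp)
    sensitivity = tp / (tp + fn)          (recall)
    specificity = tn / (tn + fp)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)
    """
    if cm.total == 0:
        raise ParameterError("empty confusion matrix: all counts are zero")
    undefined: List[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    sensitivity = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if precision == 0.0 and sensitivity == 0.0:
        f1 = 0.0
    elif math.isnan(precision) or math.isnan(sensitivity):
        undefined.append("f1")
        f1 = float("nan")
    elif precision + sensitivity == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass(frozen=True)
class CVPlan:
    """k-fold plan: seeded shuffle then contiguous fold slicing."""

    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise PlanError(f"k must be >= 2, got {self.k!r}")


def kfold(n: int, plan: CVPlan) -> List[np.ndarray]:
    """Validation-fold index sets: disjoint, exhaustive, sizes differ <= 1.

    Each fold in turn is the validation set while the remaining k-1 folds
    train; the returned list holds the k validation index arrays.
    """
    if plan.k > n:
        raise PlanError(f"k={plan.k} exceeds the sample count n={n}")
    splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return [val_idx for _, val_idx in splitter.split(np.arange(n))]


# ---------------------------------------------------------------------------
# ROC


def roc(y_true: Sequence[int], scores: Sequence[float]) -> Tuple[np.ndarray, float]:
    """Threshold-sweep ROC curve and trapezoid AUC.

    Sweeps the unique score values as decision thresholds (predict
    positive when score >= threshold), producing points from (0, 0) to
    (1, 1) non-decreasing in both coordinates.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise SignalError(
            f"length mismatch: {len(y_true)} labels vs {len(scores)} scores"
        )
    pos = int(np.sum(y_true == 1))
    neg = int(np.sum(y_true == 0))
    if pos == 0 or neg == 0:
        raise DegenerateROCError("ROC requires both classes to be present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / pos]
    fpr = np.r_[0.0, fps[distinct] / neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


# ---------------------------------------------------------------------------
# rule network


@dataclass(frozen=True)
class RuleDecision:
    """Outcome of one rule-network evaluation."""

    klass: int
    matched: bool
    hidden: Dict[str, Optional[float]] = field(default_factory=dict)
    outputs: Tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class RuleNetwork:
    """Hand-crafted rule interpretation of a small feed-forward classifier.

    Seven binary inputs I1..I7 feed three hidden nodes with discrete
    activation sets H1 in {-1, 0, 1}, H2 in {0, 1}, H3 in {-1, 0.24, 1},
    which feed an output pair (O1, O2).  The published rule list is
    incomplete (no rule ever assigns H1), so any input not matched by a
    classification rule falls back to ``default_class`` and is flagged.
    """

    default_class: int = 0
    h1_domain: Tuple[float, ...] = (-1.0, 0.0, 1.0)
    h2_domain: Tuple[float, ...] = (0.0, 1.0)
    h3_domain: Tuple[float, ...] = (-1.0, 0.24, 1.0)

    def infer_hidden(self, inputs: Dict[str, int]) -> Dict[str, Optional[float]]:
        """Apply the input -> hidden rules; unassigned nodes stay None."""
        h: Dict[str, Optional[float]] = {"H1": None, "H2": None, "H3": None}
        if inputs["I2"] == 0 and inputs["I7"] == 0:
            h["H2"] = 0.0
        if inputs["I4"] == 1 and inputs["I6"] == 1:
            h["H3"] = -1.0
        if inputs["I5"] == 0:
            h["H3"] = -1.0
        return h

    def infer_outputs(self, hidden: Dict[str, Optional[float]]) -> Tuple[int, int]:
        """Hidden -> output rules; (O1, O2) = (1, 0) on a match, else (0, 1)."""
        h1, h2, h3 = hidden["H1"], hidden["H2"], hidden["H3"]
        if (
            (h2 == 0 and h3 == -1)
            or (h1 == -1 and h2 == 1 and h3 == -1)
            or (h1 == -1 and h2 == 0 and h3 == 0.24)
        ):
            return (1, 0)
        return (0, 1)


def evaluate_rule_network(
    inputs: Dict[str, int], net: Optional[RuleNetwork] = None
) -> RuleDecision:
    """Classify one binary input assignment I1..I7 through the rule network.

    The two classification rules are tried in their published order —

        IF I2=0 AND I7=0 AND I4=1 AND I6=1  THEN class = 0
        IF I2=0 AND I7=0 AND I5=0           THEN class = 1

    — and an input firing neither rule returns the configured default
    class with ``matched=False``.
    """
    net = net or RuleNetwork()
    required = [f"I{j}" for j in range(1, 8)]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise DomainError(f"missing inputs: {missing}")
    for k in required:
        if inputs[k] not in (0, 1):
            raise DomainError(f"input {k}={inputs[k]!r} outside its domain {{0, 1}}")
    hidden = net.infer_hidden(inputs)
    outputs = net.infer_outputs(hidden)
    if inputs["I2"] == 0 and inputs["I7"] == 0 and inputs["I4"] == 1 and inputs["I6"] == 1:
        return RuleDecision(klass=0, matched=True, hidden=hidden, outputs=outputs)
    if inputs["I2"] == 0 and inputs["I7"] == 0 and inputs["I5"] == 0:
        return RuleDecision(klass=1, matched=True, hidden=hidden, outputs=outputs)
    return RuleDecision(
        klass=net.default_class, matched=False, hidden=hidden, outputs=outputs
    )


# ---------------------------------------------------------------------------
# benchmark harness


def default_grids() -> Dict[str, dict]:
    """Hyperparameter grids searched inside the cross-validation."""
    return {
        "DT": {"max_depth": [5, 10, None]},
        # wider tree grid standing in for the Bayes-optimized tree family
        "OBT": {"max_depth": [3, 5, 10, None], "min_samples_leaf": [1, 5, 20]},
        "NBT": {"var_smoothing": [1e-9, 1e-7]},
        "NeNT": {"n_neighbors": [3, 5, 11]},
        "ET": {"n_estimators": [25, 50]},
        "NNT": {"alpha": [1e-4, 1e-2]},
    }


def _make_estimator(family: str, seed: int):
    if family in ("DT", "OBT"):
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if family == "NBT":
        return GaussianNB()
    if family == "NeNT":
        return KNeighborsClassifier(metric="euclidean")
    if family == "ET":
        return AdaBoostClassifier(random_state=seed)
    if family == "NNT":
        return MLPClassifier(
            activation="relu",
            hidden_layer_sizes=(16,),
            max_iter=400,
            random_state=seed,
        )
    raise ConfigurationError(
        f"unknown classifier family {family!r}; choose from {FAMILIES}"
    )


@dataclass
class BenchmarkEntry:
    """One family's benchmark outcome."""

    family: str
    confusion: ConfusionMatrix
    report: MetricsReport
    best_params: dict
    train_seconds: float

    def to_report_dict(self) -> dict:
        cm = self.confusion
        return {
            "confusion": [cm.tp, cm.tn, cm.fp, cm.fn],
            "accuracy_pct": self.report.accuracy_pct,
            "precision": round(self.report.precision, 4),
            "sensitivity": round(self.report.sensitivity, 4),
            "specificity": round(self.report.specificity, 4),
            "f1": round(self.report.f1, 4),
            "auc": round(self.report.auc, 4),
            "train_seconds": self.train_seconds,
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
        }


def preprocess(
    train: BreathTable, test: BreathTable
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fit z-score and one-hot on train only; apply both to test."""
    numeric = train.numeric_columns()
    train_z, zparams = zscore(train, numeric)
    test_frame = zparams.transform(test.frame)
    out_train = train_z.frame
    for col in train.categorical_columns():
        train_tab, registry = one_hot(BreathTable(out_train), col)
        out_train = train_tab.frame
        test_frame = registry.transform(test_frame)
    return out_train, test_frame


def run_benchmark(
    table: BreathTable,
    families: Optional[Sequence[str]] = None,
    plan: Optional[CVPlan] = None,
    grids: Optional[Dict[str, dict]] = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> Dict[str, BenchmarkEntry]:
    """Fit and score each classifier family on one breath table.

    The table is split 70/30 stratified by mode label; preprocessing
    (z-score, one-hot) is fitted on the training split only.  Each family
    is tuned by grid search inside seeded 5-fold cross-validation on the
    training split and evaluated once on the held-out split, yielding its
    confusion matrix, metric set, ROC curve/AUC and wall-clock training
    time.  Fully deterministic given ``seed``.
    """
    families = tuple(families) if families is not None else FAMILIES
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ConfigurationError(f"unknown families requested: {sorted(unknown)}")
    plan = plan or CVPlan(seed=seed)
    all_grids = default_grids()
    if grids:
        all_grids.update(grids)
    train, test = split(table, train_fraction=train_fraction, seed=seed)
    x_train_frame, x_test_frame = preprocess(train, test)
    y_train = x_train_frame.pop(LABEL_COLUMN).to_numpy()
    y_test = x_test_frame.pop(LABEL_COLUMN).to_numpy()
    x_train = x_train_frame.to_numpy(dtype=float)
    x_test = x_test_frame[x_train_frame.columns].to_numpy(dtype=float)

    results: Dict[str, BenchmarkEntry] = {}
    for family in families:
        grid = all_grids.get(family)
        if not grid:
            raise ConfigurationError(f"empty hyperparameter grid for {family!r}")
        estimator = _make_estimator(family, seed)
        cv = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        search = GridSearchCV(estimator, grid, scoring="accuracy", cv=cv, n_jobs=1)
        t0 = time.perf_counter()
        search.fit(x_train, y_train)
        train_seconds = time.perf_counter() - t0
        y_pred = search.predict(x_test)
        scores = search.predict_proba(x_test)[:, 1]
        cm = confusion(y_test, y_pred)
        report = metrics(cm)
        report.training_time = train_seconds
        report.roc_points, report.auc = roc(y_test, scores)
        results[family] = BenchmarkEntry(
            family=family,
            confusion=cm,
            report=report,
            best_params=search.best_params_,
            train_seconds=train_seconds,
        )
    return results
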