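"""Cross-validated evaluation of candidate experts (gene set x classifier).

Each candidate expert is one classifier family trained on the covered member
genes of one enriched gene set. Experts are scored by pooling out-of-fold
predictions into a single confusion matrix and deriving Cohen's kappa,
accuracy and one-vs-rest precision/recall/specificity/F-measure from it.
A cell where the learner cannot be fit is recorded as an ERROR marker with
its cause instead of aborting the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Literal, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_io import ExpressionDataset
from .enrichment import EnrichedGeneSet

FAMILIES = ("knn", "decision_tree", "svm", "naive_bayes", "random_forest")

FAMILY_DISPLAY = {
    "knn": "k-Nearest Neighbours",
    "decision_tree": "Decision Tree",
    "svm": "Support Vector Machine",
    "naive_bayes": "Naive Bayes",
    "random_forest": "Random Forest",
}


class ExpertTrainingError(RuntimeError):
    """A classifier could not be trained for one grid cell."""


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier configuration: family plus hyperparameter overrides."""

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    config_id: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if not self.config_id:
            object.__setattr__(self, "config_id", self.family)

    def build(self, random_state: int | None = None):
        """Instantiate an unfitted scikit-learn estimator for this config."""
        params = dict(self.hyperparameters)
        if self.family == "knn":
            params.setdefault("n_neighbors", 1)
            return KNeighborsClassifier(**params)
        if self.family == "decision_tree":
            params.setdefault("criterion", "entropy")  # C4.5-style split
            params.setdefault("random_state", random_state)
            return DecisionTreeClassifier(**params)
        if self.family == "svm":
            params.setdefault("kernel", "rbf")
            params.setdefault("C", 1.0)
            params.setdefault("gamma", "scale")
            params.setdefault("random_state", random_state)
            return SVC(**params)
        if self.family == "naive_bayes":
            return GaussianNB(**params)
        params.setdefault("n_estimators", 100)
        params.setdefault("random_state", random_state)
        return RandomForestClassifier(**params)


def default_classifier_configs(rf_trees: int = 100) -> list[ClassifierConfig]:
    """One default configuration per supported family."""
    return [
        ClassifierConfig("knn", {"n_neighbors": 1}, "IBK#1"),
        ClassifierConfig("decision_tree", {}, "DT#1"),
        ClassifierConfig("svm", {}, "SVM#1"),
        ClassifierConfig("naive_bayes", {}, "NBS#1"),
        ClassifierConfig("random_forest", {"n_estimators": rf_trees}, "RF#1"),
    ]


@dataclass(frozen=True)
class ValidationScheme:
    """Out-of-fold evaluation scheme: LOOCV or seeded stratified k-fold."""

    kind: Literal["loocv", "stratified_kfold"] = "stratified_kfold"
    folds: int = 5
    seed: int = 17

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "stratified_kfold"):
            raise ValueError(f"unknown validation scheme {self.kind!r}")
        if self.kind == "stratified_kfold" and self.folds < 2:
            raise ValueError("stratified k-fold needs folds >= 2")

    def validate_for(self, labels: Sequence[str]) -> None:
        if self.kind == "stratified_kfold":
            _, counts = np.unique(np.asarray(labels), return_counts=True)
            if self.folds > counts.min():
                raise ValueError(
                    f"folds={self.folds} exceeds the smallest class count "
                    f"({counts.min()})"
                )

    def splits(self, labels: np.ndarray):
        if self.kind == "loocv":
            return LeaveOneOut().split(np.zeros((labels.size, 1)))
        cv = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        return cv.split(np.zeros((labels.size, 1)), labels)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted class."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_predictions(cls, classes: Sequence[str], y_true: Sequence[str],
                         y_pred: Sequence[str]) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)))
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(list(classes), counts)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    When the chance agreement p_e equals 1 (all mass in one true/predicted
    pair) the statistic is defined as 1 for perfect agreement and 0 otherwise.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(np.dot(row, col))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class MetricSet:
    """Kappa, accuracy and one-vs-rest per-class metrics with macro averages."""

    kappa: float
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]

    def as_flat_dict(self) -> dict[str, float]:
        flat = {"kappa": self.kappa, "accuracy": self.accuracy}
        for metric, value in self.macro.items():
            flat[f"macro_{metric}"] = value
        return flat


def class_metrics(cm: ConfusionMatrix) -> MetricSet:
    """One-vs-rest precision/recall/specificity/F per class plus accuracy and kappa.

    A class that is never predicted has precision 0 by convention; F is 0
    when precision and recall are both 0.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(cm.classes):
        tp = cm.counts[i, i]
        fp = cm.counts[:, i].sum() - tp
        fn = cm.counts[i, :].sum() - tp
        tn = n - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
        f_measure = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_class[cls] = {
            "precision": float(precision),
            "recall": float(recall),
            "specificity": float(specificity),
            "f_measure": float(f_measure),
        }
    macro = {
        metric: float(np.mean([per_class[c][metric] for c in cm.classes]))
        for metric in ("precision", "recall", "specificity", "f_measure")
    }
    return MetricSet(
        kappa=cohen_kappa(cm),
        accuracy=float(np.trace(cm.counts) / n),
        per_class=per_class,
        macro=macro,
    )


# ---------------------------------------------------------------------------
# Cross-validation and the evaluation grid
# ---------------------------------------------------------------------------

def _impute_train_means(x_train: np.ndarray, x_other: np.ndarray | None = None):
    """Replace NaN cells by per-feature training means; fail on all-NaN features."""
    means = np.nanmean(x_train, axis=0) if x_train.size else np.array([])
    if np.isnan(means).any():
        bad = int(np.flatnonzero(np.isnan(means))[0])
        raise ExpertTrainingError(
            f"feature column {bad} has no observed values in the training fold"
        )
    out_train = np.where(np.isnan(x_train), means, x_train)
    if x_other is None:
        return out_train, means
    return out_train, np.where(np.isnan(x_other), means, x_other)


def cross_validate_expert(dataset: ExpressionDataset, features: Sequence[str],
                          config: ClassifierConfig,
                          scheme: ValidationScheme) -> ConfusionMatrix:
    """Pool out-of-fold predictions of one candidate expert into a confusion matrix.

    Deterministic given the scheme seed and the configuration; every sample
    is predicted exactly once. Learner failures raise
    :class:`ExpertTrainingError` (mapped to ERROR cells by the grid).
    """
    dataset.require_training()
    if not features:
        raise ExpertTrainingError("gene set has no usable features in this dataset")
    scheme.validate_for(dataset.class_labels)
    x = dataset.feature_matrix(features)
    y = np.asarray(dataset.class_labels)
    classes = dataset.classes

    y_true: list[str] = []
    y_pred: list[str] = []
    for train_idx, test_idx in scheme.splits(y):
        try:
            x_train, x_test = _impute_train_means(x[train_idx], x[test_idx])
            model = config.build(random_state=scheme.seed)
            model.fit(x_train, y[train_idx])
            pred = model.predict(x_test)
        except ExpertTrainingError:
            raise
        except Exception as exc:  # degenerate folds, solver failures, ...
            raise ExpertTrainingError(
                f"classifier could not be trained ({exc})"
            ) from exc
        y_true.extend(y[test_idx])
        y_pred.extend(pred)
    return ConfusionMatrix.from_predictions(classes, y_true, y_pred)


@dataclass
class ErrorCell:
    """Marker for a grid cell whose expert could not be trained."""

    reason: str

    def __str__(self) -> str:
        return f"ERROR: {self.reason}"


@dataclass
class EvaluationGrid:
    """(gene set x classifier config) matrix of MetricSet or ERROR cells."""

    rows: list[EnrichedGeneSet]
    columns: list[ClassifierConfig]
    cells: list[list[MetricSet | ErrorCell]]
    scheme: ValidationScheme

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.rows) or any(
            len(r) != len(self.columns) for r in self.cells
        ):
            raise ValueError("grid cells must form a |rows| x |columns| matrix")

    @property
    def n_cells(self) -> int:
        return len(self.rows) * len(self.columns)

    def cell(self, set_id: str, config_id: str) -> MetricSet | ErrorCell:
        i = next(i for i, r in enumerate(self.rows) if r.set_id == set_id)
        j = next(j for j, c in enumerate(self.columns) if c.config_id == config_id)
        return self.cells[i][j]

    def error_count(self) -> int:
        return sum(isinstance(c, ErrorCell) for row in self.cells for c in row)

    def metric_value(self, i: int, j: int, metric: str = "kappa") -> float | None:
        cell = self.cells[i][j]
        if isinstance(cell, ErrorCell):
            return None
        return cell.as_flat_dict()[metric] if metric.startswith("macro_") else getattr(cell, metric)


def _evaluate_cell(dataset, enriched_set, config, scheme):
    if not enriched_set.usable_features:
        return ErrorCell(
            "the classifier could not be trained: the dataset contains none of "
            "the gene set's genes"
        )
    try:
        cm = cross_validate_expert(dataset, enriched_set.usable_features, config, scheme)
        return class_metrics(cm)
    except ExpertTrainingError as exc:
        return ErrorCell(str(exc))


def evaluate_grid(dataset: ExpressionDataset, enriched: Sequence[EnrichedGeneSet],
                  configs: Sequence[ClassifierConfig],
                  scheme: ValidationScheme | None = None,
                  n_workers: int = 1) -> EvaluationGrid:
    """Evaluate every (gene set, classifier config) pair.

    ``n_workers`` only parallelizes the independent cells; each cell is a
    pure function of its inputs, so results are identical for any worker
    count.
    """
    if not enriched or not configs:
        raise ValueError("evaluate_grid needs at least one gene set and one config")
    scheme = scheme or ValidationScheme()
    pairs = [(r, c) for r in enriched for c in configs]
    if n_workers > 1:
        flat = Parallel(n_jobs=n_workers, prefer="threads")(
            delayed(_evaluate_cell)(dataset, r, c, scheme) for r, c in pairs
        )
    else:
        flat = [_evaluate_cell(dataset, r, c, scheme) for r, c in pairs]
    k = len(configs)
    cells = [list(flat[i * k : (i + 1) * k]) for i in range(len(enriched))]
    return EvaluationGrid(rows=list(enriched), columns=list(configs),
                          cells=cells, scheme=scheme)
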