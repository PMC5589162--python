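"""Classifier training, SVM tuning, the metric panel and balanced evaluation.

Four algorithms are supported: logistic regression, random forest,
extremely randomized trees (both with 1000 trees), and an RBF-kernel SVM
whose (C, gamma) pair is tuned on the validation split over the grid
C in {0.1, 1, 10} x gamma in {0.01, 0.001, 0.0001, 0.00001}.  SVM inputs
are always standardized to the training split's mean and standard
deviation; the scaler travels with the fitted model.

Jogging is the positive class in all precision/recall-type metrics; AUC is
computed from continuous scores (probabilities or decision values).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import JOGGING, NONJOGGING, FeatureMatrix, ValidationError

__all__ = [
    "ALGORITHMS",
    "SVM_C_GRID",
    "SVM_GAMMA_GRID",
    "ModelSpec",
    "ModelEvaluation",
    "FittedModel",
    "train",
    "tune_svm",
    "evaluate",
    "train_and_evaluate",
    "balanced_evaluation",
    "balanced_indices",
]

ALGORITHMS = ("logistic", "random_forest", "extremely_randomized_trees", "svm_rbf")
SVM_C_GRID = (0.1, 1.0, 10.0)
SVM_GAMMA_GRID = (0.01, 0.001, 0.0001, 0.00001)


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    trees: int = 1000
    C: Optional[float] = None
    gamma: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "svm_rbf" and (self.C is None or self.gamma is None):
            raise ValidationError("svm_rbf requires tuned (C, gamma)")


def _estimator(spec: ModelSpec):
    if spec.algorithm == "logistic":
        # library-default ridge penalty; documented, kept fixed across runs
        return LogisticRegression(max_iter=1000)
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.trees, max_features="sqrt", random_state=spec.seed, n_jobs=1
        )
    if spec.algorithm == "extremely_randomized_trees":
        return ExtraTreesClassifier(
            n_estimators=spec.trees, max_features="sqrt", random_state=spec.seed, n_jobs=1
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=spec.C, gamma=spec.gamma, random_state=spec.seed)),
        ]
    )


@dataclass
class FittedModel:
    spec: ModelSpec
    features: List[str]
    estimator: object
    train_seconds: float

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        return np.asarray(self.estimator.predict(matrix.X(self.features)))

    def scores(self, matrix: FeatureMatrix) -> np.ndarray:
        """Continuous scores for the positive (jogging) class."""
        X = matrix.X(self.features)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            classes = list(est.classes_)
            return proba[:, classes.index(JOGGING)]
        return np.asarray(est.decision_function(X))


def train(matrix: FeatureMatrix, features: Sequence[str], spec: ModelSpec) -> FittedModel:
    """Fit one classifier on a feature subset of the training matrix."""
    if len(np.unique(matrix.y)) < 2:
        raise ValidationError("training labels contain a single class")
    est = _estimator(spec)
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(matrix.X(features), matrix.y)
    return FittedModel(spec, list(features), est, time.perf_counter() - t0)


def tune_svm(
    train_m: FeatureMatrix,
    validation: FeatureMatrix,
    features: Sequence[str],
    seed: int = 0,
) -> Tuple[float, float]:
    """Grid-search (C, gamma) by validation accuracy; ties prefer smaller C,
    then smaller gamma."""
    best: Optional[Tuple[float, float, float]] = None
    for C in sorted(SVM_C_GRID):
        for gamma in sorted(SVM_GAMMA_GRID):
            spec = ModelSpec("svm_rbf", C=C, gamma=gamma, seed=seed)
            model = train(train_m, features, spec)
            acc = float(np.mean(model.predict(validation) == validation.y))
            # ties broken toward smaller C, then smaller gamma
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    assert best is not None
    return best[1], best[2]


@dataclass
class ModelEvaluation:
    accuracy: float
    auc: Optional[float]
    precision: float
    recall: float
    specificity: float
    f1: float
    seconds: float = 0.0

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "seconds": self.seconds,
        }


def _panel(y: np.ndarray, pred: np.ndarray, scores: Optional[np.ndarray]) -> ModelEvaluation:
    tp = int(np.sum((pred == JOGGING) & (y == JOGGING)))
    fp = int(np.sum((pred == JOGGING) & (y == NONJOGGING)))
    fn = int(np.sum((pred == NONJOGGING) & (y == JOGGING)))
    tn = int(np.sum((pred == NONJOGGING) & (y == NONJOGGING)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if scores is not None and len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, scores))
    else:
        if scores is not None:
            warnings.warn("AUC undefined on a single-class evaluation set")
        auc = None
    return ModelEvaluation(
        accuracy=float(np.mean(pred == y)),
        auc=auc,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
    )


def evaluate(model: FittedModel, test: FeatureMatrix) -> ModelEvaluation:
    """Accuracy, AUC, precision, recall, specificity and F1 on a test matrix."""
    t0 = time.perf_counter()
    pred = model.predict(test)
    scores = model.scores(test)
    ev = _panel(test.y, pred, scores)
    ev.seconds = model.train_seconds + (time.perf_counter() - t0)
    return ev


def train_and_evaluate(
    train_m: FeatureMatrix,
    test: FeatureMatrix,
    features: Sequence[str],
    spec: ModelSpec,
) -> Tuple[FittedModel, ModelEvaluation]:
    model = train(train_m, features, spec)
    return model, evaluate(model, test)


def balanced_indices(
    matrix: FeatureMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Row indices of a per-participant balanced subsample.

    For each participant all jogging instances are kept and an equal number
    of that participant's non-jogging instances is drawn without
    replacement.  Participants with no jogging instances are skipped.
    """
    participants = matrix.features.index.get_level_values(0).to_numpy()
    keep: List[np.ndarray] = []
    for pid in pd.unique(participants):
        rows = np.flatnonzero(participants == pid)
        pos = rows[matrix.y[rows] == JOGGING]
        neg = rows[matrix.y[rows] == NONJOGGING]
        if pos.size == 0:
            continue
        if neg.size < pos.size:
            raise ValidationError(
                f"participant {pid} has fewer non-jogging than jogging instances"
            )
        keep.append(pos)
        keep.append(rng.choice(neg, size=pos.size, replace=False))
    if not keep:
        raise ValidationError("no participants with jogging instances")
    return np.sort(np.concatenate(keep))


def balanced_evaluation(
    train_m: FeatureMatrix,
    validation: FeatureMatrix,
    test: FeatureMatrix,
    features: Sequence[str],
    spec: ModelSpec,
    repetitions: int = 100,
    seed: int = 0,
    retune_svm: bool = True,
) -> Tuple[ModelEvaluation, List[ModelEvaluation]]:
    """Stratified under-sampling evaluation, averaged over repetitions.

    Per repetition each split is balanced per participant, the model is
    trained on the balanced training set (the SVM re-tuned on the balanced
    validation set unless ``retune_svm`` is False) and evaluated on the
    balanced test set.  Returns the metric means and the per-repetition
    panels.
    """
    rng = np.random.default_rng(seed)
    panels: List[ModelEvaluation] = []
    for _ in range(repetitions):
        b_train = train_m.take(balanced_indices(train_m, rng))
        b_val = validation.take(balanced_indices(validation, rng))
        b_test = test.take(balanced_indices(test, rng))
        run_spec = spec
        if spec.algorithm == "svm_rbf" and retune_svm:
            C, gamma = tune_svm(b_train, b_val, features, seed=spec.seed)
            run_spec = replace(spec, C=C, gamma=gamma)
        model = train(b_train, features, run_spec)
        panels.append(evaluate(model, b_test))
    aucs = [p.auc for p in panels if p.auc is not None]
    mean = ModelEvaluation(
        accuracy=float(np.mean([p.accuracy for p in panels])),
        auc=float(np.mean(aucs)) if aucs else None,
        precision=float(np.mean([p.precision for p in panels])),
        recall=float(np.mean([p.recall for p in panels])),
        specificity=float(np.mean([p.specificity for p in panels])),
        f1=float(np.mean([p.f1 for p in panels])),
        seconds=float(np.sum([p.seconds for p in panels])),
    )
    return mean, panels
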