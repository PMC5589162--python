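"""Drift-aware feature selection.

Four stages:

1. **Series screen** — average tree-ensemble importance per original time
   series; series more than 3x less informative than the best are discarded
   with all their features.
2. **Drift sensitivity** — an artificial origin-classification task (did a
   row come from the training or the validation split?) is fit with an
   extremely-randomized-trees ensemble; its feature importances estimate how
   sensitive each feature is to distribution drift between splits.
3. **Percentile grid screen** — all 81 combinations of importance and drift
   percentile thresholds (10..90) are evaluated with a logistic-regression
   wrapper; features need high importance AND low drift to survive.
4. **Diversified forward-backward (DFB) wrapper selection** — greedy
   additions in importance-rank order with a permanent blacklist for failed
   additions, alternating with backward removal passes, under a budget on
   the number of evaluated feature sets (2000 by default).

All ensembles use 1000 trees with sqrt(n_features) candidate features per
split; improvement is strict, so accepted-move traces are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .io import FeatureMatrix, ValidationError
from .names import location_of_feature, parent_series

__all__ = [
    "ImportanceReport",
    "FeatureSet",
    "ert_importances",
    "series_screen",
    "drift_sensitivity",
    "percentile_grid_screen",
    "dfb_select",
    "select_features",
    "location_columns",
]

N_TREES = 1000
GRID_PERCENTILES = tuple(range(10, 100, 10))


def _wrapper() -> LogisticRegression:
    return LogisticRegression(max_iter=500)


def _fit_score(
    train: FeatureMatrix, validation: FeatureMatrix, features: Sequence[str]
) -> float:
    """Validation accuracy of the logistic wrapper on a candidate feature set."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = _wrapper().fit(train.X(features), train.y)
    return float(np.mean(clf.predict(validation.X(features)) == validation.y))


def ert_importances(
    matrix: FeatureMatrix, y: Optional[np.ndarray] = None, seed: int = 0
) -> pd.Series:
    """Impurity importances from a 1000-tree extremely-randomized ensemble."""
    clf = ExtraTreesClassifier(
        n_estimators=N_TREES, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(matrix.X(), matrix.y if y is None else y)
    return pd.Series(clf.feature_importances_, index=matrix.feature_names)


@dataclass
class ImportanceReport:
    feature_importances: pd.Series
    series_importances: pd.Series  # average importance per parent series

    @property
    def max_series(self) -> str:
        return str(self.series_importances.idxmax())


def series_screen(
    matrix: FeatureMatrix, seed: int = 0, ratio: float = 3.0
) -> Tuple[List[str], ImportanceReport]:
    """Discard series whose average feature importance is > ``ratio`` times
    below the most informative series; returns (retained series, report)."""
    imp = ert_importances(matrix, seed=seed)
    groups: Dict[str, List[float]] = {}
    for name, value in imp.items():
        series = parent_series(str(name))
        if series is not None:
            groups.setdefault(series, []).append(float(value))
    series_avg = pd.Series({s: float(np.mean(v)) for s, v in groups.items()})
    cutoff = series_avg.max() / ratio
    retained = [s for s in series_avg.index if series_avg[s] >= cutoff]
    return retained, ImportanceReport(imp, series_avg)


def drift_sensitivity(
    train: FeatureMatrix, validation: FeatureMatrix, seed: int = 0
) -> pd.Series:
    """Feature importances on the artificial origin-label (train vs validation)
    task; high values flag features that are unstable across splits."""
    if train.feature_names != validation.feature_names:
        raise ValidationError("train and validation have different columns")
    X = np.vstack([train.X(), validation.X()])
    origin = np.concatenate(
        [np.zeros(train.n_instances, int), np.ones(validation.n_instances, int)]
    )
    clf = ExtraTreesClassifier(
        n_estimators=N_TREES, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(X, origin)
    return pd.Series(clf.feature_importances_, index=train.feature_names)


@dataclass
class FeatureSet:
    """An ordered selected feature set with its selection provenance."""

    features: List[str]
    validation_accuracy: float
    provenance: Dict = field(default_factory=dict)
    trace: List[Dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValidationError("feature set contains duplicates")

    def __len__(self) -> int:
        return len(self.features)


def percentile_grid_screen(
    importances: pd.Series,
    drifts: pd.Series,
    train: FeatureMatrix,
    validation: FeatureMatrix,
) -> FeatureSet:
    """Evaluate all 81 (importance, drift) percentile-threshold pairs.

    A feature survives a combination when its importance is at or above the
    importance percentile AND its drift sensitivity is at or below the drift
    percentile.  Each surviving set is scored by logistic-regression
    validation accuracy; ties prefer fewer features, then a stricter (lower)
    drift threshold.
    """
    imp = importances.reindex(train.feature_names)
    dri = drifts.reindex(train.feature_names)
    imp_cuts = {p: np.percentile(imp.to_numpy(), p) for p in GRID_PERCENTILES}
    dri_cuts = {p: np.percentile(dri.to_numpy(), p) for p in GRID_PERCENTILES}
    best: Optional[Tuple[float, int, int, int, List[str]]] = None
    skipped = []
    for p_imp in GRID_PERCENTILES:
        for p_dri in GRID_PERCENTILES:
            mask = (imp >= imp_cuts[p_imp]) & (dri <= dri_cuts[p_dri])
            candidates = [str(c) for c in imp.index[mask]]
            if not candidates:
                skipped.append((p_imp, p_dri))
                continue
            acc = _fit_score(train, validation, candidates)
            key = (-acc, len(candidates), p_dri, p_imp)
            if best is None or key < (-best[0], best[1], best[2], best[3]):
                best = (acc, len(candidates), p_dri, p_imp, candidates)
    if best is None:
        raise ValidationError("all threshold combinations produced empty sets")
    acc, n_feat, p_dri, p_imp, candidates = best
    return FeatureSet(
        features=candidates,
        validation_accuracy=acc,
        provenance={
            "stage": "percentile_grid_screen",
            "importance_percentile": p_imp,
            "drift_percentile": p_dri,
            "combinations_evaluated": 81 - len(skipped),
            "skipped_combinations": skipped,
        },
    )


def dfb_select(
    candidates: Sequence[str],
    train: FeatureMatrix,
    validation: FeatureMatrix,
    max_sets: int = 2000,
) -> FeatureSet:
    """Diversified forward-backward wrapper selection.

    ``candidates`` must be ranked by importance (descending).  Forward pass:
    each eligible candidate is tentatively added to the current best set and
    kept only on strict validation-accuracy improvement; a failed addition
    permanently blacklists the feature.  Backward pass: each member is
    tentatively removed (in addition order), restarting the pass on strict
    improvement.  Passes alternate until neither improves or ``max_sets``
    wrapper evaluations have been spent.  The empty set scores as the
    majority-class validation accuracy.
    """
    if not candidates:
        raise ValidationError("empty candidate list")
    majority = int(np.bincount(train.y).argmax())
    best_score = float(np.mean(validation.y == majority))
    current: List[str] = []
    blacklist: set = set()
    evaluations = 0
    trace: List[Dict] = [{"move": "init", "score": best_score, "size": 0}]

    def score(features: List[str]) -> float:
        nonlocal evaluations
        evaluations += 1
        return _fit_score(train, validation, features)

    improved_cycle = True
    while improved_cycle and evaluations < max_sets:
        improved_cycle = False
        # forward pass
        for f in candidates:
            if evaluations >= max_sets:
                break
            if f in current or f in blacklist:
                continue
            s = score(current + [f])
            if s > best_score:
                current = current + [f]
                best_score = s
                improved_cycle = True
                trace.append({"move": "add", "feature": f, "score": s, "size": len(current)})
            else:
                blacklist.add(f)
                trace.append({"move": "reject", "feature": f, "score": s, "size": len(current)})
        # backward pass: restart after each successful removal
        removed = True
        while removed and evaluations < max_sets and len(current) > 1:
            removed = False
            for f in list(current):
                if evaluations >= max_sets:
                    break
                trial = [g for g in current if g != f]
                s = score(trial)
                if s > best_score:
                    current = trial
                    best_score = s
                    improved_cycle = True
                    removed = True
                    trace.append(
                        {"move": "remove", "feature": f, "score": s, "size": len(current)}
                    )
                    break
    return FeatureSet(
        features=current,
        validation_accuracy=best_score,
        provenance={"stage": "dfb", "evaluations": evaluations, "max_sets": max_sets},
        trace=trace,
    )


def location_columns(matrix: FeatureMatrix, location: str) -> List[str]:
    """Columns usable for a sensor-location-restricted run.

    ``"all"`` keeps every column; ``"ankle"``/``"hip"`` keep features whose
    parent series belongs to that location (gender and cross-sensor features
    are excluded from single-location runs).
    """
    if location == "all":
        return matrix.feature_names
    if location not in ("ankle", "hip"):
        raise ValidationError(f"unknown location tag {location!r}")
    return [c for c in matrix.feature_names if location_of_feature(c) == location]


def select_features(
    train: FeatureMatrix,
    validation: FeatureMatrix,
    location: str = "all",
    seed: int = 0,
    max_sets: int = 2000,
) -> FeatureSet:
    """The full drift-aware chain on a (possibly location-restricted) matrix:
    importance + drift estimation, percentile grid screen, DFB selection."""
    cols = location_columns(train, location)
    tr, va = train.select(cols), validation.select(cols)
    importances = ert_importances(tr, seed=seed)
    drifts = drift_sensitivity(tr, va, seed=seed)
    screened = percentile_grid_screen(importances, drifts, tr, va)
    ranked = sorted(
        screened.features, key=lambda f: (-float(importances[f]), screened.features.index(f))
    )
    selected = dfb_select(ranked, tr, va, max_sets=max_sets)
    selected.provenance.update(
        {
            "location": location,
            "grid": screened.provenance,
            "screened_size": len(screened),
        }
    )
    return selected
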