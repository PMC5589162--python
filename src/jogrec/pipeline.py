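"""End-to-end experiment orchestration.

``run_experiment`` ties the stages together: segment and label a cohort,
fit the training-split histogram bins and gender encoding, extract the
original-series features, screen out uninformative series, build the merged
feature set, run drift-aware feature selection per sensor location, train
and evaluate the classifiers, and finally convert the best model's window
predictions into jogging periods, apply the post-classification rules and
score the period matching ratio against the golden standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import JOGGING, NONJOGGING, FeatureMatrix, ValidationError
from .features import WoETable, extract_original_features, fit_bins
from .modeling import (
    ALGORITHMS,
    FittedModel,
    ModelEvaluation,
    ModelSpec,
    evaluate,
    train,
    tune_svm,
)
from .periods import (
    ActivityPeriod,
    MatchingReport,
    apply_rule,
    matching_ratio,
    periods_from_track,
    timeline_to_periods,
    vote_merge,
)
from .segmentation import EXCLUDED, SegmentedDataset, WindowSpec, build_dataset
from .selection import FeatureSet, location_columns, select_features
from .synthetic import SynthCohort
from .transforms import (
    extract_baseline_features,
    extract_full_features,
    fit_delta_bins,
    fit_derivative_bins,
)

__all__ = ["PipelineData", "LocationResult", "ExperimentReport", "prepare_matrices", "run_experiment", "period_evaluation", "diary_matching"]

RULES = ("none", "rule1", "rule2", "rule3")


@dataclass
class PipelineData:
    """Feature matrices and bookkeeping shared by all experiment variants."""

    spec: WindowSpec
    label_source: str
    retained_series: List[str]
    matrices: Dict[str, FeatureMatrix]          # labeled, excluded windows removed
    baseline_matrices: Dict[str, FeatureMatrix]
    test_all: FeatureMatrix                     # every test window (for timelines)
    test_all_baseline: FeatureMatrix
    dataset_counts: Dict[str, Dict[str, float]]


def _sanitize(ds: SegmentedDataset) -> SegmentedDataset:
    """Excluded windows get a placeholder label so extraction can run on them."""
    labels = np.where(ds.labels == EXCLUDED, NONJOGGING, ds.labels).astype(np.int8)
    return SegmentedDataset(ds.spec, ds.index, labels, ds.gender, ds.series)


def prepare_matrices(
    cohort: SynthCohort,
    spec: WindowSpec,
    label_source: str = "golden",
    seed: int = 0,
    energy: str = "squared",
) -> PipelineData:
    """Segment, screen series and extract the merged feature set per split."""
    datasets = build_dataset(cohort, spec, label_source, drop_excluded=False)
    masks = {s: ds.labels != EXCLUDED for s, ds in datasets.items()}
    clean = {s: _sanitize(ds) for s, ds in datasets.items()}

    train_mask = masks["train"]
    woe = WoETable().fit(
        datasets["train"].gender[train_mask], datasets["train"].labels[train_mask]
    )
    bins = fit_bins(clean["train"])

    original = {
        s: extract_original_features(clean[s], bins, woe, energy=energy)
        for s in datasets
    }
    from .selection import series_screen  # local import avoids a cycle at import time

    retained, _report = series_screen(
        original["train"].take(np.flatnonzero(train_mask)), seed=seed
    )
    delta_bins = fit_delta_bins(clean["train"], retained)
    deriv_bins = fit_derivative_bins(clean["train"], retained)

    full = {
        s: extract_full_features(
            clean[s], retained, bins, delta_bins, deriv_bins, woe, energy=energy
        )
        for s in datasets
    }
    baseline = {s: extract_baseline_features(clean[s], retained) for s in datasets}

    matrices = {s: full[s].take(np.flatnonzero(masks[s])) for s in datasets}
    baseline_m = {s: baseline[s].take(np.flatnonzero(masks[s])) for s in datasets}
    counts = {
        s: {
            "jogging": int(np.sum(datasets[s].labels == JOGGING)),
            "nonjogging": int(np.sum(datasets[s].labels == NONJOGGING)),
            "excluded": int(np.sum(datasets[s].labels == EXCLUDED)),
            "jogging_ratio": float(
                np.sum(datasets[s].labels == JOGGING)
                / max(np.sum(datasets[s].labels != EXCLUDED), 1)
            ),
        }
        for s in datasets
    }
    return PipelineData(
        spec=spec,
        label_source=label_source,
        retained_series=retained,
        matrices=matrices,
        baseline_matrices=baseline_m,
        test_all=full["test"],
        test_all_baseline=baseline["test"],
        dataset_counts=counts,
    )


@dataclass
class LocationResult:
    location: str
    feature_set: FeatureSet
    evaluations: Dict[str, ModelEvaluation]
    best_algorithm: str
    best_model: FittedModel
    svm_params: Tuple[float, float]
    matching: Dict[str, MatchingReport] = field(default_factory=dict)


def _evaluate_location(
    data: PipelineData,
    features: Sequence[str],
    algorithms: Sequence[str],
    seed: int,
    refit_train_val: bool,
) -> Tuple[Dict[str, ModelEvaluation], str, FittedModel, Tuple[float, float]]:
    tr, va, te = (data.matrices[s] for s in ("train", "validation", "test"))
    fit_matrix = tr
    if refit_train_val:
        merged = pd.concat([tr.features, va.features])
        fit_matrix = FeatureMatrix(merged, np.concatenate([tr.labels, va.labels]))
    C, gamma = (None, None)
    evaluations: Dict[str, ModelEvaluation] = {}
    models: Dict[str, FittedModel] = {}
    for algo in algorithms:
        if algo == "svm_rbf":
            C, gamma = tune_svm(tr, va, features, seed=seed)
            spec = ModelSpec(algo, C=C, gamma=gamma, seed=seed)
        else:
            spec = ModelSpec(algo, seed=seed)
        model = train(fit_matrix, features, spec)
        models[algo] = model
        evaluations[algo] = evaluate(model, te)
    best = max(algorithms, key=lambda a: (evaluations[a].accuracy, -algorithms.index(a)))
    return evaluations, best, models[best], (C, gamma)


def _day_groups(index: pd.MultiIndex):
    participants = index.get_level_values(0)
    days = index.get_level_values(1).normalize()
    return pd.Series(np.arange(len(index)), index=index).groupby(
        [participants, days], sort=True
    )


def period_evaluation(
    data: PipelineData,
    model: FittedModel,
    cohort: SynthCohort,
    use_baseline: bool = False,
) -> Dict[str, MatchingReport]:
    """Pooled matching reports (per rule) of a model's test-split predictions.

    Window predictions over *all* test windows (including border windows)
    are vote-merged per participant-day into a 60 s timeline; each rule is
    applied to both the predicted and the golden period lists before
    matching, and reports are pooled over participant-days.
    """
    matrix = data.test_all_baseline if use_baseline else data.test_all
    preds = model.predict(matrix)
    golden = cohort.labels("golden")
    pooled = {rule: MatchingReport(0, 0, 0) for rule in RULES}
    for (pid, day), rows in _day_groups(matrix.features.index):
        idx = rows.to_numpy()
        starts = matrix.features.index.get_level_values(1)[idx]
        timeline = vote_merge(starts, preds[idx], data.spec, participant_id=pid)
        predicted = timeline_to_periods(timeline)
        day_end = day + pd.Timedelta(days=1)
        gold_periods = [
            ActivityPeriod(s, e)
            for s, e in golden[pid].intervals
            if s >= day and e <= day_end
        ]
        for rule in RULES:
            pooled[rule] = pooled[rule] + matching_ratio(
                apply_rule(predicted, rule), apply_rule(gold_periods, rule)
            )
    return pooled


def diary_matching(cohort: SynthCohort, split: str = "test") -> Dict[str, MatchingReport]:
    """Diary-vs-golden matching (per rule) pooled over a split's participants."""
    pooled = {rule: MatchingReport(0, 0, 0) for rule in RULES}
    for entry in cohort.split(split):
        diary = periods_from_track(entry.diary)
        gold = periods_from_track(entry.golden)
        for rule in RULES:
            pooled[rule] = pooled[rule] + matching_ratio(
                apply_rule(diary, rule), apply_rule(gold, rule)
            )
    return pooled


@dataclass
class ExperimentReport:
    spec: WindowSpec
    label_source: str
    featureset_source: str
    retained_series: List[str]
    dataset_counts: Dict[str, Dict[str, float]]
    locations: Dict[str, LocationResult]
    diary: Dict[str, MatchingReport]

    def as_dict(self) -> Dict:
        def mr(d: Dict[str, MatchingReport]) -> Dict:
            return {
                r: {
                    "matched": m.matched,
                    "missed": m.missed,
                    "other": m.other,
                    "matching_ratio": m.matching_ratio,
                }
                for r, m in d.items()
            }

        return {
            "window_length_s": self.spec.length_s,
            "overlap_s": self.spec.overlap_s,
            "label_source": self.label_source,
            "featureset_source": self.featureset_source,
            "retained_series": self.retained_series,
            "dataset_counts": self.dataset_counts,
            "locations": {
                loc: {
                    "n_features": len(res.feature_set),
                    "features": res.feature_set.features,
                    "best_algorithm": res.best_algorithm,
                    "svm_params": res.svm_params,
                    "evaluations": {a: e.as_dict() for a, e in res.evaluations.items()},
                    "matching": mr(res.matching),
                }
                for loc, res in self.locations.items()
            },
            "diary_matching": mr(self.diary),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, default=str)


def run_experiment(
    cohort: SynthCohort,
    spec: WindowSpec,
    label_source: str = "golden",
    locations: Sequence[str] = ("ankle", "hip", "all", "union"),
    featureset_source: str = "proposed",
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    max_sets: int = 2000,
    refit_train_val: bool = False,
    data: Optional[PipelineData] = None,
) -> ExperimentReport:
    """Run the full pipeline for the requested sensor-location variants.

    ``locations`` may contain ``ankle``, ``hip``, ``all`` and ``union`` (the
    union of the best ankle and best hip sets; requires both to be present).
    ``featureset_source='baseline'`` skips selection and uses the five
    power-spectrum coefficients per retained series instead.
    """
    if featureset_source not in ("proposed", "baseline"):
        raise ValidationError(f"unknown featureset source {featureset_source!r}")
    if data is None:
        data = prepare_matrices(cohort, spec, label_source, seed=seed)
    algorithms = list(algorithms)
    results: Dict[str, LocationResult] = {}
    single = [loc for loc in locations if loc != "union"]
    for loc in single:
        if featureset_source == "proposed":
            fs = select_features(
                data.matrices["train"], data.matrices["validation"], loc, seed, max_sets
            )
        else:
            cols = location_columns(data.baseline_matrices["train"], loc)
            fs = FeatureSet(cols, float("nan"), provenance={"stage": "baseline"})
        results[loc] = _make_location_result(
            data, cohort, loc, fs, algorithms, seed, refit_train_val, featureset_source
        )
    if "union" in locations:
        for need in ("ankle", "hip"):
            if need not in results:
                raise ValidationError("union variant requires ankle and hip runs")
        union_features = list(
            dict.fromkeys(
                results["ankle"].feature_set.features + results["hip"].feature_set.features
            )
        )
        fs = FeatureSet(union_features, float("nan"), provenance={"stage": "union"})
        results["union"] = _make_location_result(
            data, cohort, "union", fs, algorithms, seed, refit_train_val, featureset_source
        )
    return ExperimentReport(
        spec=spec,
        label_source=label_source,
        featureset_source=featureset_source,
        retained_series=data.retained_series,
        dataset_counts=data.dataset_counts,
        locations=results,
        diary=diary_matching(cohort),
    )


def _make_location_result(
    data: PipelineData,
    cohort: SynthCohort,
    location: str,
    fs: FeatureSet,
    algorithms: Sequence[str],
    seed: int,
    refit_train_val: bool,
    featureset_source: str,
) -> LocationResult:
    use_baseline = featureset_source == "baseline"
    if use_baseline:
        # swap in the baseline matrices for training/evaluation
        data = PipelineData(
            spec=data.spec,
            label_source=data.label_source,
            retained_series=data.retained_series,
            matrices=data.baseline_matrices,
            baseline_matrices=data.baseline_matrices,
            test_all=data.test_all_baseline,
            test_all_baseline=data.test_all_baseline,
            dataset_counts=data.dataset_counts,
        )
    evaluations, best, model, svm_params = _evaluate_location(
        data, fs.features, algorithms, seed, refit_train_val
    )
    matching = period_evaluation(data, model, cohort, use_baseline=use_baseline)
    return LocationResult(
        location=location,
        feature_set=fs,
        evaluations=evaluations,
        best_algorithm=best,
        best_model=model,
        svm_params=svm_params,
        matching=matching,
    )
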