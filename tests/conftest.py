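"""Shared fixtures: a small fast cohort and one session-scoped full run."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jogrec.pipeline import prepare_matrices, run_experiment
from jogrec.segmentation import WindowSpec, build_dataset
from jogrec.synthetic import SynthConfig, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_config(seed: int = 7) -> SynthConfig:
    """Two participants per split, short 2-hour days: fast to segment."""
    return SynthConfig(
        seed=seed,
        n_train=2,
        n_validation=2,
        n_test=2,
        gender_counts={"train": (1, 1), "validation": (1, 1), "test": (1, 1)},
        day_minutes=120,
        bouts_per_day=(1,),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_dataset_60(small_cohort):
    return build_dataset(small_cohort, WindowSpec(60, 0))


@pytest.fixture(scope="session")
def small_dataset_180(small_cohort):
    return build_dataset(small_cohort, WindowSpec(180, 120))


@pytest.fixture(scope="session")
def e2e():
    """One full pipeline run at a desk-scale problem size (4-hour days,
    one bout per day); shared by the end-to-end and balanced-evaluation
    tests so the expensive stages run once per session."""
    config = SynthConfig(seed=1, day_minutes=240, bouts_per_day=(1,))
    cohort = generate_cohort(config)
    spec = WindowSpec(60, 0)
    data = prepare_matrices(cohort, spec, seed=1)
    report = run_experiment(cohort, spec, locations=("ankle",), seed=1, data=data)
    return cohort, data, report


@pytest.fixture()
def rng():
    return np.random.default_rng(20161031)
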