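import numpy as np
import pytest

from chipdyn import (CohortSimConfig, Trajectory, TrajectoryObservation,
                     simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A fixed 20-subject simulated cohort shared across read-only tests."""
    cfg = CohortSimConfig(n_subjects=20, seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trajectory(ages, vafs, depths, subject="S1", gene="DNMT3A",
                    variant="1:100:A:G"):
    obs = [
        TrajectoryObservation(age=float(a), vaf=float(v), depth=int(d),
                              alt_count=int(round(v * d)))
        for a, v, d in zip(ages, vafs, depths)
    ]
    return Trajectory(subject_id=subject, gene=gene, variant_id=variant,
                      observations=obs)


@pytest.fixture
def trajectory_factory():
    return make_trajectory
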