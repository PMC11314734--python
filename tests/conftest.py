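import numpy as np
import pytest

from toecurve import default_profiles, features_table, simulate_cohort


def random_trial_arrays(rng, n=None):
    """A random plausible force trial: time grid plus non-negative forces,
    occasionally with ties or constant stretches."""
    n = n or int(rng.integers(5, 500))
    dt = 0.02
    time = dt * np.arange(1, n + 1)
    kind = rng.integers(0, 4)
    if kind == 0:  # smooth rise + noise
        tau = rng.uniform(0.1, 3.0)
        force = rng.uniform(5, 80) * (1 - np.exp(-time / tau))
        force = np.clip(force * (1 + rng.normal(0, 0.05, n)), 0, None)
    elif kind == 1:  # white positive noise
        force = rng.uniform(0, 50, n)
    elif kind == 2:  # constant with plateaus/ties
        force = np.round(rng.uniform(1, 30, n))
    else:  # step function
        force = np.where(time < rng.uniform(0.1, time[-1]), rng.uniform(0, 5),
                         rng.uniform(10, 60))
    if force.max() <= 0:
        force[-1] = 1.0
    return time, force


@pytest.fixture(scope="session")
def cohort():
    """Default-profile synthetic cohort (31 subjects), fixed seed."""
    return simulate_cohort(default_profiles(), seed=20240)


@pytest.fixture(scope="session")
def feature_frame(cohort):
    table, degenerate = features_table(cohort.trials, cohort.subjects)
    assert not degenerate
    return table
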