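"""Shared fixtures: analytic tracks and reusable synthetic cohorts."""

import numpy as np
import pytest

from fluokin.config import RunConfig
from fluokin.kinematics import Track
from fluokin.pipeline import extract_cohort_features
from fluokin.synthetic_data import generate_cohort


def make_min_jerk_track(
    amplitude_mm: float = 100.0,
    duration_s: float = 1.0,
    rate_hz: float = 500.0,
    direction=(1.0, 0.0, 0.0),
    n_reaches: int = 1,
) -> Track:
    """Noise-free track of one or more sequential minimum-jerk reaches."""
    n = int(round(duration_s * rate_hz))
    tau = np.arange(1, n + 1) / n
    prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    pos = [np.zeros(3)]
    for _ in range(n_reaches):
        start = pos[-1]
        pos.extend(list(start + amplitude_mm * prof[:, None] * d))
    pos = np.array(pos)
    t = np.arange(len(pos)) / rate_hz
    return Track(
        t_s=t, x_mm=pos[:, 0], y_mm=pos[:, 1], z_mm=pos[:, 2],
        mode=np.zeros(len(pos), int),
    )


def straight_track(n: int = 100, rate_hz: float = 30.0, speed_mmps: float = 20.0) -> Track:
    t = np.arange(n) / rate_hz
    return Track(t_s=t, x_mm=speed_mmps * t, y_mm=np.zeros(n), z_mm=np.zeros(n),
                 mode=np.zeros(n, int))


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=42, n_exercises=40)


@pytest.fixture(scope="session")
def cohort40(run_config):
    """40-exercise default cohort (both error and error-free exercises)."""
    return generate_cohort(40, master_seed=run_config.seed)


@pytest.fixture(scope="session")
def features40(cohort40, run_config):
    return extract_cohort_features(cohort40, run_config)


@pytest.fixture(scope="session")
def cohort200():
    """200-exercise default cohort for distributional checks."""
    return generate_cohort(200, master_seed=42)


@pytest.fixture(scope="session")
def features200(cohort200):
    return extract_cohort_features(cohort200, RunConfig(seed=42))
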