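import numpy as np
import pandas as pd
import pytest

from trackstress.synthetic_data import (
    GeneratorConfig, MSDTruth, generate_task_schedule, noise_free_config,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A 6-subject study with default (realistic-noise) settings."""
    return simulate_study(GeneratorConfig(n_subjects=6, seed=11))


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, jitter-free, gap-free generator for exact-recovery checks."""
    return noise_free_config(
        seed=5,
        true_msd={"tRelaxed": MSDTruth(0.5, 8.0), "tStressed": MSDTruth(0.5, 8.0)},
        stroke_duration_s=6.0,
    )


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    """The largest-distance trial spec under the clean config."""
    sched = generate_task_schedule("S01", "tRelaxed", clean_config)
    return next(s for s in sched if s.task_config.distance_px == 1024)


def make_events(t, x, y=None, finger_id=0, major=8.0, minor=6.0):
    """Hand-built event frame for constructed segmentation/metric cases."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.full_like(t, 35.0) if y is None else np.asarray(y, dtype=float)
    fid = np.full(t.shape, finger_id, dtype=int) if np.isscalar(finger_id) else np.asarray(finger_id)
    return pd.DataFrame({
        "t_s": t, "finger_id": fid, "x_mm": x, "y_mm": y,
        "major_mm": np.full_like(t, major), "minor_mm": np.full_like(t, minor),
        "state": "touching", "pressed": True,
    })
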