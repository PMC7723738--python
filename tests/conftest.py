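import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from breathverify import BreathTrace, SensorParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_trace(samples, pre=5, test_id="T1", **kwargs) -> BreathTrace:
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    return BreathTrace(
        test_id=test_id,
        participant_id="P01",
        timestamp=pd.Timestamp("2024-03-01 10:00"),
        samples=samples,
        sample_rate=5.0,
        duration=n / 5.0,
        pre_exhalation_count=pre,
        **kwargs,
    )


def step_trace(baseline: float, plateau: float, n_base=25, n_plateau=75) -> BreathTrace:
    """Clean step: flat baseline segment then flat plateau, no noise."""
    samples = np.concatenate(
        [np.full(n_base, baseline), np.full(n_plateau, plateau)]
    )
    return make_trace(samples, pre=n_base)


def random_trace(rng: np.random.Generator) -> BreathTrace:
    """A noisy synthetic trace with random baseline, plateau and shape."""
    pre = int(rng.integers(1, 15))
    n = 100
    baseline = float(rng.uniform(0, 6))
    plateau = float(rng.uniform(0, 25))
    noise = rng.normal(0, rng.uniform(0, 1.0), size=n)
    ramp = np.concatenate(
        [np.zeros(pre), np.linspace(0, 1, 5), np.ones(n - pre - 5)]
    )
    samples = np.clip(baseline + plateau * ramp + noise, 0, None)
    return make_trace(samples, pre=pre)


@pytest.fixture
def noiseless_sensor() -> SensorParams:
    return SensorParams.noiseless()
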