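import numpy as np
import pandas as pd
import pytest

from ybalance.io import TrialSignal
from ybalance.synthetic import SyntheticStudySpec


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def small_spec():
    """Reduced study: 5 subjects, 2 trials, short trials, angle channels only."""
    return SyntheticStudySpec(
        n_subjects=5,
        n_trials=2,
        duration_s=4.0,
        channels=("ankle_AP", "ankle_ML"),
        seed=11,
    )


@pytest.fixture
def toy_table():
    """5 subjects x 3 conditions measure table with known hand-computed ANOVA."""
    y = np.array(
        [
            [1.0, 2.0, 3.0],
            [2.0, 4.0, 3.0],
            [5.0, 6.0, 7.0],
            [3.0, 3.0, 4.0],
            [2.0, 5.0, 6.0],
        ]
    )
    rows = [
        {"subject": f"s{i}", "condition": cond, "channel": "ch", "measure": "m", "value": y[i, j]}
        for i in range(5)
        for j, cond in enumerate(["NT", "ST", "KT"])
    ]
    return pd.DataFrame(rows), y


def make_signal(values, rate=100.0, channel="ankle_AP", subject="s1", condition="NT", trial=1):
    return TrialSignal(
        subject=subject, condition=condition, trial=trial, channel=channel, rate=rate,
        values=np.asarray(values, dtype=float),
    )


@pytest.fixture
def signal_factory():
    return make_signal
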