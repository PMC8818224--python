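import numpy as np
import pandas as pd
import pytest

from collaraccel.devicesim import (SessionPlan, compose_session,
                                   default_behaviour_specs)


@pytest.fixture(scope="session")
def specs():
    return default_behaviour_specs()


@pytest.fixture(scope="session")
def small_session(specs):
    """One short mixed session at the ideal rate with known ground truth."""
    plan = SessionPlan(
        segments=(("lie", 12.0), ("stand", 8.0), ("walk", 10.0),
                  ("gallop", 8.0), ("standing stalk", 6.0), ("trot", 8.0)),
        rail_window=8.0, noise_sd=0.05, seed=42)
    trace, labels = compose_session(plan, specs)
    return plan, trace, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_separable_dataset(n_per_class=120, n_classes=4, seed=0,
                           informative="static_heave"):
    """Synthetic 14-predictor dataset where one channel carries the signal.

    Classes sit at well-separated values of the informative predictor;
    every other channel is pure noise.
    """
    from collaraccel.features import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_classes):
        df = pd.DataFrame(
            rng.normal(0, 1, size=(n_per_class, len(FEATURE_COLUMNS))),
            columns=FEATURE_COLUMNS)
        df[informative] = k * 10.0 + rng.normal(0, 0.1, n_per_class)
        df["behaviour"] = f"class{k}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
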