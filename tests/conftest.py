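import numpy as np
import pandas as pd
import pytest

from recumbency.synthetic import (
    ALL_RECUMBENT,
    SOME_ACTIVE,
    BehaviorScenario,
    GaussianSpec,
    PenConfig,
    sample_velocity_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_pen():
    return PenConfig(pen_id="pen01", n_animals=6, frame_interval_s=1.0)


@pytest.fixture
def alternating_scenario():
    """30-minute alternating states over 2 h, starting active."""
    return BehaviorScenario(
        duration_s=7200.0,
        state_schedule=(
            (0.0, SOME_ACTIVE),
            (1800.0, ALL_RECUMBENT),
            (3600.0, SOME_ACTIVE),
            (5400.0, ALL_RECUMBENT),
        ),
        seed=99,
    )


@pytest.fixture
def still_scenario():
    """A single recumbent state with zero jitter and no false detections."""
    return BehaviorScenario(
        duration_s=600.0,
        state_schedule=((0.0, ALL_RECUMBENT),),
        recumbent_jitter_dist=GaussianSpec(0.0, 0.0),
        false_detection_rate=0.0,
        seed=5,
    )


@pytest.fixture
def mixture_samples():
    """4000 window velocities from the two-state mixture at defaults."""
    return sample_velocity_dataset(4000, seed=31)


def label_table(codes, coder_id="A", pen_id="pen01"):
    """Coder table from a plain list of codes, keys t = 0, 1, 2, ..."""
    return pd.DataFrame(
        {
            "pen_id": pen_id,
            "t_s": np.arange(len(codes), dtype=float),
            "coder_id": coder_id,
            "code": list(codes),
        }
    )
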