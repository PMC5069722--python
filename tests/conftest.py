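"""Shared fixtures: small synthetic datasets and feature matrices.

Everything is generated programmatically at collection time; sizes are kept
small enough that the whole suite runs in minutes on one core.
"""

import numpy as np
import pandas as pd
import pytest

from emgsel.dataset import MOTION_CLASSES, ChannelLayout, Trial
from emgsel.evaluation import EvalConfig, build_feature_matrix
from emgsel.features import FeatureMatrix
from emgsel.synth import default_layout, generate_dataset, preset


@pytest.fixture(scope="session")
def tiny_layout() -> ChannelLayout:
    return default_layout(2, 1)


@pytest.fixture(scope="session")
def trial_factory(tiny_layout):
    """Build a labelled trial from an explicit signal array."""

    def make(signal, motion_class="open", position="neutral", rep=1, layout=None):
        layout = layout or tiny_layout
        return Trial(
            subject_id="s1",
            motion_class=motion_class,
            wrist_position=position,
            repetition=rep,
            signal=np.asarray(signal, dtype=float),
            layout=layout,
        )

    return make


@pytest.fixture(scope="session")
def intact_trials(tiny_layout):
    """Small intact-like dataset: 2 extrinsic + 1 intrinsic, 2 repetitions."""
    return generate_dataset(
        preset("intact-like", layout=tiny_layout, repetitions=2, seed=11)
    )


@pytest.fixture(scope="session")
def intact_fm(intact_trials):
    """TDAR feature matrix of the small intact-like dataset (sparse windows)."""
    cfg = EvalConfig(seed=11, increment_ms=200.0)
    return build_feature_matrix(intact_trials, "combined", "TDAR", cfg)


def random_feature_matrix(
    n_per_class: int = 12,
    channels: tuple[str, ...] = ("ext1", "ext2"),
    features: tuple[str, ...] = ("MAV", "RMS", "WL"),
    seed: int = 0,
    class_shift: float = 0.0,
) -> FeatureMatrix:
    """Labelled feature matrix with i.i.d. Gaussian values (plus an optional
    per-class mean shift on every column), for selection/split tests."""
    rng = np.random.default_rng(seed)
    columns = [(ch, f) for ch in channels for f in features]
    rows = []
    values = []
    for k, mc in enumerate(MOTION_CLASSES):
        values.append(
            rng.standard_normal((n_per_class, len(columns))) + class_shift * k
        )
        for i in range(n_per_class):
            rows.append(
                {
                    "subject": "s1",
                    "motion_class": mc,
                    "wrist_position": "neutral",
                    "repetition": 1 + i // 4,
                    "start_offset": i,
                }
            )
    return FeatureMatrix(
        values=np.vstack(values),
        columns=columns,
        labels=pd.DataFrame(rows),
    )


@pytest.fixture
def gaussian_fm():
    return random_feature_matrix(seed=3)
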