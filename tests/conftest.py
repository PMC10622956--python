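"""Shared fixtures: small synthetic configurations that keep training fast.

The scaled-down geometry (8 channels, 125 Hz, 2.5 s trials, small filter
counts) exercises exactly the same code paths as the canonical 22 x 1,000
stack; the canonical geometry itself is checked symbolically and, where the
arithmetic demands it, on full-size generated data.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecaselect.network import Hyperparameters, build_eca_deepnet, train_model
from ecaselect.selection import split_by_trial
from ecaselect.simulate import SimConfig, generate_sampleset

SMALL_FILTERS = (8, 8, 16, 16)
SMALL_KERNEL = 6
SMALL_POOL = 2


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    kwargs = dict(
        n_channels=8,
        sampling_rate_hz=125.0,
        trial_seconds=2.5,
        pre_cue_seconds=0.5,
        gap_seconds=1.0,
        n_trials_per_class=10,
        n_classes=4,
        informative_channels={0: (1,), 1: (3,), 2: (5,), 3: (7,)},
        erd_depth=0.8,
        rhythm_rms=20.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def small_spec(channels: int = 8, time_samples: int = 250, classes: int = 4):
    return build_eca_deepnet(
        channels,
        time_samples,
        classes,
        filters=SMALL_FILTERS,
        temporal_kernel=SMALL_KERNEL,
        pool_size=SMALL_POOL,
    )


def fast_hp(**overrides) -> Hyperparameters:
    kwargs = dict(
        epochs=8,
        batch_size=16,
        learning_rate=3e-3,
        dropout_rate=0.2,
        weight_decay=1e-4,
        seed=11,
    )
    kwargs.update(overrides)
    return Hyperparameters(**kwargs)


@pytest.fixture(scope="session")
def small_sampleset():
    """80 crops of shape (8, 250): 10 trials x 4 classes x 2 crops."""
    ss, gt = generate_sampleset(
        small_sim_config(), window_samples=250, stride_samples=62
    )
    return ss, gt


@pytest.fixture(scope="session")
def small_split(small_sampleset):
    ss, _ = small_sampleset
    return split_by_trial(ss, 0.2, seed=3)


@pytest.fixture(scope="session")
def small_trained(small_split):
    """A small model trained once and shared by read-only tests."""
    train_ss, _ = small_split
    spec = small_spec(train_ss.n_channels, train_ss.n_times, 4)
    return train_model(train_ss, fast_hp(epochs=30), spec=spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
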