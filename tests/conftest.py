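"""Shared fixtures: task configuration, epoch windows, small seeded sessions."""

import numpy as np
import pytest

from wmcrys import (GeneratorConfig, Session, TaskConfig, Trial,
                    build_epoch_windows, generate_cohort)


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def windows(task):
    return build_epoch_windows(task)


def make_session(activity, trials=None, animal_id="m01", day=1,
                 centroids=None, locomotion=None, frame_rate=None):
    """Wrap a raw activity tensor in a Session with default metadata."""
    activity = np.asarray(activity, dtype=float)
    nt, nn, _ = activity.shape
    if trials is None:
        types = ["AC", "AD", "BC", "BD"]
        trials = [Trial(trial_type=types[i % 4], licked=(i % 4) in (0, 3))
                  for i in range(nt)]
    if centroids is None:
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1000, size=(nn, 2))
        depth = rng.uniform(30, 450, size=nn)
        centroids = np.column_stack([xy, depth])
    return Session(animal_id=animal_id, day_index=day, trials=trials,
                   activity=activity, neuron_ids=np.arange(nn),
                   centroids=centroids, locomotion=locomotion,
                   frame_rate=frame_rate)


@pytest.fixture()
def random_session(task):
    """20 trials x 6 neurons of nonnegative noise at the default task shape."""
    rng = np.random.default_rng(7)
    act = rng.exponential(0.3, size=(20, 6, task.n_frames))
    return make_session(act)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 animals x 3 days, small enough for fast pipeline tests."""
    cfg = GeneratorConfig(n_animals=2, n_days=3, n_neurons=25,
                          trials_per_day=40, crystallization_day=2,
                          detection_dropout=0.0, seed=42)
    return generate_cohort(cfg)
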