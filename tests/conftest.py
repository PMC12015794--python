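"""Shared fixtures: one small simulated cohort reused across test modules."""

import numpy as np
import pytest

import mannerkit as mk


@pytest.fixture(scope="session")
def small_cohort():
    """4-subject, 12 s clean cohort (no confidence dropout)."""
    cfg = mk.default_cohort(
        n_subjects=4, segment_duration_s=12.0, seed=7, dropout_prob=0.0
    )
    return mk.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    return mk.windows_from_sim(small_cohort)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with the default 5% confidence dropout, walker included."""
    cfg = mk.default_cohort(
        n_subjects=3, segment_duration_s=12.0, seed=11, dropout_prob=0.05
    )
    return mk.simulate_cohort(cfg)


def make_window(subject="s01", camera="cam1", start=0, label=(0, 0),
                source=None, unclear=False, fill=0.0):
    """Build a Window with constant features for splitter/balancer tests."""
    from mannerkit.annotations import MannerismType

    if source is None:
        source = set()
        if label[0]:
            source.add(MannerismType.FLAPPING)
        if label[1]:
            source.add(MannerismType.JUMPING)
    return mk.Window(
        subject_id=subject, camera_id=camera, start_frame=start,
        features=np.full((15, 60), fill),
        label=mk.LabelVector(*label),
        source_labels=frozenset(source), unclear=unclear,
    )
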