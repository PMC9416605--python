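import numpy as np
import pytest

from semgband import (
    CohortSpec,
    assemble_matrix,
    segment_session,
    synth_cohort,
    synth_session,
)


@pytest.fixture(scope="session")
def default_session():
    """One default-timing single-arm session with ground truth."""
    return synth_session("S01", "left", seed=11)


@pytest.fixture(scope="session")
def default_segments(default_session):
    return segment_session(default_session.record)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 2 arms x 3 cycles x 6 movements = 108 instances."""
    return synth_cohort(CohortSpec(n_subjects=3, seed=5))


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    segments = []
    for ss in small_cohort:
        segments.extend(segment_session(ss.record))
    return segments


@pytest.fixture(scope="session")
def small_avg_dataset(small_segments):
    return assemble_matrix(small_segments, mode="average")


def best_label(instances, source_range):
    """Ground-truth movement whose slot overlaps a segment's source range most."""
    a, b = source_range
    return max(instances,
               key=lambda inst: max(0, min(b, inst["end"]) - max(a, inst["start"])))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
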