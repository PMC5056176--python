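import numpy as np
import pytest

from playdyn import fixture
from playdyn.core import SegmentRating
from playdyn.scoring import ALL_ITEMS


@pytest.fixture(scope="session")
def table4_sequences():
    return fixture("table4_sequences")


@pytest.fixture(scope="session")
def table3_centers():
    return fixture("table3_centers")


@pytest.fixture(scope="session")
def table1_outcomes():
    return fixture("table1_outcomes")


def make_segment(patient="P01", session=1, segment=1, activity="play",
                 score=3, duration=None, **overrides):
    """A fully rated play segment with every CPTI item at ``score``."""
    items = {item: score for item in ALL_ITEMS}
    items.update(overrides)
    return SegmentRating(patient_id=patient, session_index=session,
                         segment_index=segment, activity_type=activity,
                         item_scores=items if activity == "play" else {},
                         duration=duration)


@pytest.fixture
def rated_segment():
    return make_segment()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
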