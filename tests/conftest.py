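import numpy as np
import pytest

from m6aduet.features import FeatureConfig, extract_site_read_features
from m6aduet.io import Event, EventAlignedRead
from m6aduet.simulate import make_fixture, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(make_fixture("tiny", seed=7))


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    ds = tiny_dataset
    return list(
        extract_site_read_features(
            ds.reads, ds.alignments, ds.sites, FeatureConfig(seed=7), labels=ds.read_labels
        )
    )


def random_read(rng: np.random.Generator, read_id="readA", transcript_id="txA",
                start=0, n_events=12, max_dwell=8) -> EventAlignedRead:
    """A random but valid event-aligned read for round-trip / property tests."""
    events = []
    for i in range(n_events):
        n_sig = int(rng.integers(1, max_dwell + 1))
        sig = tuple(float(x) for x in rng.normal(90, 10, n_sig))
        base = "ACGT"[rng.integers(4)]
        events.append(Event(start + i, base, sig))
    return EventAlignedRead(read_id, transcript_id, events)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
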