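import pytest

from picoshrink.fixtures import FixtureParams, generate_read_snapshot


@pytest.fixture(scope="session")
def small_params():
    """Small but structurally complete read: fast enough for unit tests."""
    return FixtureParams(seed=11, n_events=120, signal_samples_per_event=6)


@pytest.fixture(scope="session")
def snapshot_2d(small_params):
    return generate_read_snapshot(small_params)


@pytest.fixture()
def fresh_2d(snapshot_2d):
    snap, manifest = snapshot_2d
    return snap.copy(), manifest


def make_params(**kw):
    base = dict(seed=11, n_events=120, signal_samples_per_event=6)
    base.update(kw)
    return FixtureParams(**base)
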