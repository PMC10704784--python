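import numpy as np
import pytest

from lctcc import simulate as sim
from lctcc.types import EventSeries, SpikeTrain


@pytest.fixture(scope="session")
def naive_session():
    """One full-featured naive session, long enough for every stage except
    slow-band period estimation (which needs multi-hour recordings)."""
    cfg = sim.preset("naive", seed=4, duration=1700.0)
    return sim.generate_session(cfg)


@pytest.fixture
def meningeal_train_events():
    """50-stimulus meningeal electrical train (5 ms pulses every 2 s)."""
    return EventSeries(10.0 + np.arange(50) * 2.0, 0.005, 2.0, "meningeal")


def regular_train(rate_hz: float, duration: float, region="LC", kind="MUA"):
    times = np.arange(1, int(duration * rate_hz)) / rate_hz
    return SpikeTrain(times, region, kind, "reg")
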