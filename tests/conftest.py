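import numpy as np
import pytest

from abcdl.coalsim import RegionSpec
from abcdl.demography import SimulatorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_regions(n: int, length: int = 50_000,
                 callable_fraction: float = 1.0) -> list[RegionSpec]:
    return [RegionSpec(f"r{i}", length, round(length * callable_fraction))
            for i in range(n)]


def one_pop_spec(size: float = 10_000.0) -> SimulatorSpec:
    """Single constant-size population, no events."""
    return SimulatorSpec("toy", [("POP", size, 0.0, True)], [])


def two_pop_spec(size: float = 1_000.0, migration: float = 0.0,
                 split_time: float = 1e7) -> SimulatorSpec:
    from abcdl.demography import SimEvent
    events = [SimEvent(split_time, "split", (("P1", "P2"), "ANC"))]
    if migration > 0:
        events.insert(0, SimEvent(0.0, "migration", ("P1", "P2", migration)))
    return SimulatorSpec("toy2", [("P1", size, 0.0, True),
                                  ("P2", size, 0.0, True),
                                  ("ANC", size, 0.0, False)], events)
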