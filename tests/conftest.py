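import numpy as np
import pandas as pd
import pytest

from flowpheno.io_model import EventTable
from flowpheno.synthetic import generate_fixture_library
from flowpheno.transform import apply_panel_transform, default_panel


@pytest.fixture(scope="session")
def fixture_library():
    return generate_fixture_library()


@pytest.fixture(scope="session")
def display_events(fixture_library):
    """Fixture events transformed onto the logicle display scale, by name."""

    cache = {}

    def get(name: str) -> EventTable:
        if name not in cache:
            fx = fixture_library[name]
            panel = default_panel(fx.events.marker_names, fx.config.transform)
            cache[name] = apply_panel_transform(fx.events, panel)
        return cache[name]

    return get


def make_events(values, markers=None, sample_id="s1", batch_id="b1",
                group="A", scale="raw") -> EventTable:
    """Small EventTable helper used across the unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    markers = markers or [f"m{i+1}" for i in range(values.shape[1])]
    n = values.shape[0]
    meta = pd.DataFrame({"sample_id": [sample_id] * n,
                         "batch_id": [batch_id] * n,
                         "group": [group] * n})
    return EventTable(values, markers, meta, scale=scale)
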