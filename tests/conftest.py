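import datetime as dt

import numpy as np
import pytest

from stepcoach import (
    BehaviorResponse,
    DailyRecord,
    MessageCatalog,
)
from stepcoach.feedback import SMBPA_ITEMS


@pytest.fixture(scope="session")
def catalog() -> MessageCatalog:
    return MessageCatalog.default()


@pytest.fixture
def make_records():
    """Factory for simple daily-record series: make_records([(steps, worn), ...])."""

    def _make(days, start=dt.date(2024, 1, 1)):
        out = []
        for i, spec in enumerate(days):
            if spec is None:
                out.append(DailyRecord(date=start + dt.timedelta(days=i)))
                continue
            steps, worn = spec if isinstance(spec, tuple) else (spec, True)
            out.append(
                DailyRecord(date=start + dt.timedelta(days=i), steps=steps, worn=worn)
            )
        return out

    return _make


@pytest.fixture
def make_response():
    """BehaviorResponse with every item at `fill`, overridden per item."""

    def _make(fill=2, **overrides):
        scores = {item: fill for item in SMBPA_ITEMS}
        scores.update(overrides)
        return BehaviorResponse(scores)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
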