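from datetime import datetime, timedelta

import numpy as np
import pytest

from ethotrace.core import Bout, CageGeometry, ClassifierConfig, ExperimentConfig


@pytest.fixture
def geometry():
    return CageGeometry()


@pytest.fixture
def cfg():
    return ClassifierConfig()


@pytest.fixture
def exp():
    return ExperimentConfig()


def make_bout(
    positions,
    rate_hz: float = 5.0,
    start: datetime | None = None,
    fly_id: str = "fly",
    cage_id: int = 0,
    geometry: CageGeometry | None = None,
    labels=None,
) -> Bout:
    """Bout from raw positions; duration derived from the frame count."""
    positions = np.asarray(positions, dtype=float)
    return Bout(
        fly_id,
        cage_id,
        start if start is not None else datetime(2020, 1, 1, 12, 0, 0),
        rate_hz,
        len(positions) / rate_hz,
        positions,
        labels=labels,
        geometry=geometry if geometry is not None else CageGeometry(),
    )


def labeled_bout(labels, rate_hz=5.0, start=None, position=(75.0, 75.0, 0.0), **kw):
    """Bout of constant position with prescribed per-frame labels (for
    timeline-level tests that only consume labels)."""
    labels = np.asarray(labels, dtype=np.int8)
    pos = np.tile(np.asarray(position, dtype=float), (len(labels), 1))
    return make_bout(pos, rate_hz=rate_hz, start=start, labels=labels, **kw)
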