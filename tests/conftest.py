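"""Shared fixtures and point-cloud builders for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sdapkit.localizations import LocalizationTable


def make_table(xy, channel="A", frame=None, photons=1000.0, uncertainty=8.5):
    """LocalizationTable from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    if frame is None:
        frame = np.arange(n) % 100
    return LocalizationTable(pd.DataFrame({
        "frame": np.broadcast_to(frame, (n,)),
        "channel": channel,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "photons": photons,
        "uncertainty": uncertainty,
    }))


def ring_points(radius=100.0, n=360, center=(0.0, 0.0), theta0=0.0,
                theta1=2.0 * np.pi, endpoint=False):
    """Deterministic noiseless points on a circular arc."""
    theta = np.linspace(theta0, theta1, n, endpoint=endpoint)
    return np.column_stack([
        center[0] + radius * np.cos(theta),
        center[1] + radius * np.sin(theta),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
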