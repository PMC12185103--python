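import numpy as np
import pytest

from placeframes.geometry import PositionSeries


def series_from_angles(angles_deg, radius=20.0, fs=30.0, theta=None):
    """Position series visiting the given room-frame polar angles in order."""
    angles = np.asarray(angles_deg, dtype=float)
    t = np.arange(angles.size) / fs
    x = radius * np.cos(np.deg2rad(angles))
    y = radius * np.sin(np.deg2rad(angles))
    th = np.zeros_like(t) if theta is None else np.asarray(theta, dtype=float)
    return PositionSeries(t, x, y, th)


@pytest.fixture
def uniform_angle_series():
    """Exactly uniform angular occupancy: ten samples per 1-degree bin."""
    angles = np.repeat(np.arange(360.0) + 0.5, 10)
    return series_from_angles(angles)


@pytest.fixture
def stationary_series():
    t = np.arange(300) / 30.0
    return PositionSeries(t, np.full(300, 10.0), np.zeros(300), np.zeros(300))
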