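import numpy as np
import pytest

from mgce import LandmarkFrame, LandmarkSeries, load_config


@pytest.fixture(scope="session")
def cfg():
    return load_config()


def make_series(t, points, fps=25.0, exercise="ptosis", confidence=1.0):
    """Build a LandmarkSeries from {name: (x_array, y_array)} without noise."""
    return LandmarkSeries.from_arrays(
        np.asarray(t, dtype=float),
        {k: (np.asarray(x, dtype=float), np.asarray(y, dtype=float)) for k, (x, y) in points.items()},
        fps=fps,
        exercise=exercise,
        confidence=confidence,
    )


def make_frame(t, points):
    return LandmarkFrame(t=t, points=points)
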