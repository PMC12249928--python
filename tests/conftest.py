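import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from pbmquant.io import TrajectoryTable


def make_track(xy, delta_t=1.0, track_id="t0"):
    """One-track TrajectoryTable from a list of (x, y) points."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return TrajectoryTable(
        pd.DataFrame(
            {
                "track_id": track_id,
                "frame": np.arange(n),
                "t": np.arange(n) * delta_t,
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )
    )


@pytest.fixture
def collinear_track():
    """Four points on a line, unit spacing: msd=[1,4,9], mad=[1,2,3]."""
    return make_track([(0, 0), (1, 0), (2, 0), (3, 0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
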