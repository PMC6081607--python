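import numpy as np
import pandas as pd
import pytest

from vpcscore import CohortParams, noise_free, simulate_cohort


def make_stream(points, hz=60.0, valid=None, eye_offset=0.012):
    """Build a gaze-stream DataFrame from midpoint coordinates.

    ``points`` is an (n, 2) array of intended gaze midpoints; both eyes are
    placed symmetrically about each midpoint so the binocular midpoint
    reproduces it exactly.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    left = pts + [-eye_offset, 0.0]
    right = pts + [eye_offset, 0.0]
    left[~valid] = np.nan
    right[~valid] = np.nan
    return pd.DataFrame({
        "t_ms": np.arange(n) * 1000.0 / hz,
        "left_x": left[:, 0], "left_y": left[:, 1],
        "right_x": right[:, 0], "right_y": right[:, 1],
        "valid": valid,
    })


@pytest.fixture(scope="session")
def small_cohort():
    params = CohortParams(n_subjects=6, seed=11)
    datasets, truth = simulate_cohort(params)
    return params, datasets, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with every noise source silenced."""
    params = noise_free(CohortParams(n_subjects=4, seed=3))
    datasets, truth = simulate_cohort(params)
    return params, datasets, truth
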