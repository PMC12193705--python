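import numpy as np
import pytest

from digitrace import ScreenGeometry, sentence_word_boxes


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()

@pytest.fixture(scope="session")
def words(geometry):
    """Word boxes of the canonical 5-word sentence stimulus."""
    return sentence_word_boxes(geometry=geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trajectory(x_px, y_px, geometry, touching=None, dt_ms=None,
                    subject_id="S1", session=1, trial_id="t1"):
    """Build a Trajectory from pixel coordinates (helper for tests)."""
    from digitrace import Trajectory

    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    n = len(x_px)
    dt_ms = geometry.dt_ms if dt_ms is None else dt_ms
    if touching is None:
        touching = np.ones(n, dtype=bool)
    return Trajectory(
        subject_id=subject_id, group=1, phase=1, session=session,
        trial_id=trial_id, exercise_type="SE",
        t=np.arange(n) * dt_ms,
        x_pct=x_px / geometry.width_px * 100.0,
        y_pct=y_px / geometry.height_px * 100.0,
        touching=np.asarray(touching, dtype=bool))
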