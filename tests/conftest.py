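import numpy as np
import pytest

import vigileeg as v
from vigileeg.features import FeatureMatrix


@pytest.fixture(scope="session")
def short_recording():
    """60 s alert + 60 s drowsy, O1 and Fp1 only, seed 7."""
    rec, labels = v.generate_recording(
        [("alert", 60), ("drowsy", 60)], channels=("O1", "Fp1"), seed=7
    )
    return rec, labels


@pytest.fixture(scope="session")
def contrast_recording():
    """Alternating schedule, 120 s per state, O1 only, seed 11."""
    rec, labels = v.generate_recording(
        v.alternating_schedule(120), channels=("O1",), seed=11
    )
    return rec, labels


def make_features(X, y, r=0, channel="O1"):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return FeatureMatrix(
        X=X, y=np.asarray(y, dtype=int), r=r, channel=channel,
        band_names=tuple(f"f{j}" for j in range(X.shape[1])),
        t_index=np.arange(len(y)),
    )


@pytest.fixture
def toy_separable():
    """Linearly separable pairs straddling x1 = 1.5 (margin plane)."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
    y = np.array([-1, -1, 1, 1])
    return make_features(X, y)


@pytest.fixture
def xor_features():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    return make_features(X, y)
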