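import numpy as np
import pytest

from drowsikit.feature_extraction import FeatureVector
from drowsikit.synthetic import EventSpec, SubjectProfile, generate_session


class StubModel:
    """Deterministic stand-in classifier: labels windows by mean EAR.

    A window whose average EAR falls below the cut ratio scores as drowsy.
    Matches the TrainedModel predict/predict_score surface.
    """

    def __init__(self, n_features: int = 60, cut: float = 0.2):
        self.n_features = n_features
        self.cut = cut

    def predict_score(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ear_block = X[:, : self.n_features // 4]
        return (ear_block.mean(axis=1) < self.cut).astype(float)

    def predict(self, X):
        return (self.predict_score(X) >= 0.5).astype(int)


class ConstantModel:
    """Classifier that always emits the same label."""

    def __init__(self, label: int, n_features: int = 60):
        self.label = label
        self.n_features = n_features

    def predict_score(self, X):
        return np.full(len(np.atleast_2d(X)), float(self.label))

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.label, dtype=int)


@pytest.fixture
def stub_model():
    return StubModel()


@pytest.fixture
def constant_model():
    return ConstantModel


@pytest.fixture
def alert_fv():
    return FeatureVector(ear=0.32, mar=0.1, nose_x=320.0, nose_y=216.0)


@pytest.fixture
def drowsy_fv():
    return FeatureVector(ear=0.05, mar=0.1, nose_x=320.0, nose_y=216.0)


@pytest.fixture(scope="session")
def clean_session():
    """A 30 s noiseless session with one event per modality."""
    events = [
        EventSpec("drowsy_blink", 3.0, 0.6),
        EventSpec("yawn", 8.0, 5.0),
        EventSpec("nod", 17.0, 2.0),
        EventSpec("blink", 22.0, 0.3),
        EventSpec("talk", 24.0, 2.0),
    ]
    return generate_session(
        events,
        SubjectProfile(),
        duration_s=30.0,
        seed=7,
        jitter_sigma=0.0,
        nose_jitter_px=0.0,
    )
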