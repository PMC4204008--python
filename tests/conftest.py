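import numpy as np
import pytest

from remsef.calibration import calibrate_thresholds
from remsef.pipeline import extract_recording_features
from remsef.synth import (default_templates, sample_hypnogram,
                          synthesize_recording)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def synthetic_recording(templates):
    """A labelled 60-epoch synthetic recording shared across tests."""
    hyp = sample_hypnogram(60, seed=42, ensure_stages=("REM", "N2", "W"))
    record, hyp = synthesize_recording(hyp, templates, seed=42)
    return record, hyp


@pytest.fixture(scope="session")
def synthetic_features(synthetic_recording):
    """(features, stages) of the shared synthetic recording."""
    record, hyp = synthetic_recording
    return extract_recording_features(record, hyp)


@pytest.fixture(scope="session")
def calibrated_thresholds(synthetic_features):
    feats, stages = synthetic_features
    labels = np.array([s == "REM" for s in stages])
    return calibrate_thresholds(feats, labels)
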