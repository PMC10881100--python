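import numpy as np
import pytest

import hfonet


@pytest.fixture(scope="session")
def chain_recording():
    """A 3-channel recording with a planted 0 -> 1 -> 2 propagation chain
    (lags 5 and 10 ms) at high SNR, plus its ground truth."""
    cfg = hfonet.RecordingSimConfig(
        n_channels=3, duration=30.0, noise_sd=10.0,
        propagation_graph=[(0, 1, 5.0, 0.9), (1, 2, 10.0, 0.9)],
        n_discharges=25, event_amplitude=120.0, solitary_rate=2.0, seed=3,
    )
    return hfonet.make_recording(cfg)


@pytest.fixture(scope="session")
def chain_detections(chain_recording):
    """Accepted detections on the chain fixture.

    Widespread redaction is disabled (fraction 1.0): with only 3 channels a
    true network discharge necessarily spans more than half the montage.
    """
    rec, _ = chain_recording
    car = hfonet.common_average_reference(rec)
    p = hfonet.DetectorParams(widespread_fraction=1.0)
    events = hfonet.staba_detect(car, p)
    return hfonet.redact_artifacts(events, car, p)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
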