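import numpy as np
import pytest

from ssvephybrid import preprocessing, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def four_class_plan():
    """Small frequency/phase plan for fast end-to-end tests."""
    freqs = np.array([8.0, 10.0, 12.0, 14.0])
    phases = np.array([0.0, 0.5, 1.0, 1.5]) * np.pi
    return freqs, phases


@pytest.fixture(scope="session")
def four_class_samples(four_class_plan):
    """200 one-second 4-class trials at 20 dB SNR (50 blocks of 4)."""
    freqs, phases = four_class_plan
    cfg = synthetic.SynthConfig(
        frequencies=freqs,
        phases=phases,
        snr_db=20.0,
        channel_gains=synthetic.posterior_channel_gains(8),
        fs=250.0,
        seed=42,
    )
    rec = synthetic.synth_recording(cfg, "datasetII", 50, 2.0)
    return preprocessing.preprocess_recording(rec, preprocessing.dataset_ii_config(1.0))
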