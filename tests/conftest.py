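import numpy as np
import pytest

from pacdetect import synth


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, wander-free, metronomic all-normal rhythm."""
    return synth.SynthConfig(
        patient_id="clean",
        n_beats=100,
        rr_sd_ms=0.0,
        resp_amp_ms=0.0,
        noise_sd_mv=0.0,
        wander_amp_mv=0.0,
        kernel_jitter=0.0,
        beat_amp_jitter=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    record, truth = synth.generate_record(clean_config)
    return record, truth


@pytest.fixture(scope="session")
def mixed_record():
    """A record containing isolated PACs and PVCs, light noise."""
    cfg = synth.SynthConfig(
        patient_id="mixed",
        n_beats=140,
        pac_rate=0.10,
        pvc_rate=0.06,
        noise_sd_mv=0.01,
        seed=11,
    )
    record, truth = synth.generate_record(cfg)
    return record, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
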