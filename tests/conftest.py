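import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-participant, low-noise synthetic dataset shared across tests."""
    from crsdetect import ProtocolConfig, synthesize_dataset

    cfg = ProtocolConfig(n_participants=6, seed=3, noise_sd=0.05)
    recordings, manifest = synthesize_dataset(cfg)
    return cfg, recordings, manifest


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    from crsdetect.model import windows_from_recordings

    _, recordings, _ = small_cohort
    x, y, pids, names = windows_from_recordings(recordings)
    return x, y, np.asarray(pids), names
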