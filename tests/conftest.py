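import numpy as np
import pytest

from bloodsig.simdata import SimConfig, generate_dataset

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_sim():
    """Small batched dataset: 3 batches x (4 samples + 2 controls)."""
    cfg = SimConfig(
        n_batches=3,
        samples_per_batch=4,
        controls_per_batch=2,
        n_probes=120,
        n_signal_probes=10,
        effect_size=1.0,
        batch_sd=0.4,
        noise_sd=1.0,
        p_low_snr=0.02,
        p_bad_flag=0.005,
        n_replicate_subjects=1,
        seed=7,
    )
    return cfg, *generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default study layout (13 batches of 10 + 2), modest probe count."""
    cfg = SimConfig(n_probes=400, n_signal_probes=20, seed=11)
    return cfg, *generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
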