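import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_synth():
    """A small coupled dataset: one regime, two clusters, fast to analyze."""
    import dynfc

    cfg = dynfc.SynthConfig(
        n_channels=6,
        n_trials=20,
        fs=128.0,
        t_start_ms=-1000.0,
        t_end_ms=1000.0,
        regimes=[dynfc.Regime(-1000.0, 1000.0, [[0, 1, 2], [3, 4, 5]], 6.0)],
        sync_mod_depth=0.0,
        common_mix=0.0,
        noise_sd=0.05,
        phase_diffusion=0.3,
        seed=11,
    )
    return dynfc.generate(cfg)
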