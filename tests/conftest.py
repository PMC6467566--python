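import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """One small synthetic session shared by I/O and pipeline tests."""
    import audassoc.synth as sy

    cfg = sy.paper_like_config(
        n_blocks_per_task=1,
        trials_per_block=60,
        passive_trials_per_block=40,
        n_units=3,
        n_lfp_sites=2,
        seed=42,
    )
    units = sy.paper_like_units(3, np.random.default_rng(7), best_frequency=3000.0)
    return sy.generate_session(cfg, units=units)
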