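import numpy as np
import pytest

RECOVERY_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recovery_experiment():
    """The full ten-study parameter-recovery experiment (shared; expensive)."""
    from ecdnasim.experiments import run_parameter_recovery

    return run_parameter_recovery(RECOVERY_SEED, n_seeds=10, fits_per_study=2)
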