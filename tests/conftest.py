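import numpy as np
import pytest

from flaskkpi import SignalTrace, run_scenario


@pytest.fixture(scope="session")
def clean_ecoli_run():
    """Noiseless E. coli (defined medium) pipeline run, shared read-only."""
    return run_scenario("ecoli_biener", seed=1, noise_scale=0.0)


@pytest.fixture()
def exp_trace():
    """Noiseless exponential OUR-like trace, mu = 0.5 1/h over 8 h."""
    t = np.arange(0.0, 8.0 + 1e-9, 0.1)
    return SignalTrace(t, 1e-3 * np.exp(0.5 * t), "our")
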