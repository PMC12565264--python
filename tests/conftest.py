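import numpy as np
import pytest

from biophase import DoseScenario, expected_survival_series


@pytest.fixture
def worked_example_scenario():
    """Dose scenario reproducing the published worked-example line
    q² = 2.3056 − 0.232·T with total kill (q_r = 0)."""
    return DoseScenario(dose=50.0, t0=(2.3056 - 1.0) / 0.232, beta1=0.232, qr=0.0)


@pytest.fixture
def worked_example_series(worked_example_scenario):
    """Noise-free daily series (days 1..12) of expected counts, n = 40."""
    return expected_survival_series(worked_example_scenario, range(1, 13), n=40)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
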