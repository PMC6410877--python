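import numpy as np
import pytest
from scipy import stats


@pytest.fixture(scope="session")
def rice_sample():
    """Independent sampler of measured distances: scipy's Rice distribution.

    Used as the oracle data source so that fitter tests do not depend on the
    package's own generator.
    """

    def _sample(mu: float, sigma: float, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return stats.rice.rvs(b=mu / sigma, scale=sigma, size=n, random_state=rng)

    return _sample
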