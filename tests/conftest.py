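import numpy as np
import pytest

from fretnet.kinetics import RateSystem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rate_system(rng: np.random.Generator, n_donors: int) -> RateSystem:
    """Arbitrary positive-rate kinetic network for oracle cross-checks."""
    k_d = float(rng.uniform(0.5, 2.0))
    k_da = rng.uniform(0.0, 5.0, n_donors)
    upper = rng.uniform(0.0, 5.0, (n_donors, n_donors))
    k_dd = np.triu(upper, k=1)
    k_dd = k_dd + k_dd.T
    return RateSystem(k_da=k_da, k_dd=k_dd, k_d=k_d, k_a=0.0)
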