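import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def jc_params():
    from foramlineage import GTRIGParams

    return GTRIGParams(n_categories=1)


def random_gtrig_params(rng, k=4, with_inv=True):
    """A random valid GTR+I+G parameter set (test helper)."""
    from foramlineage import GTRIGParams

    freqs = rng.dirichlet([10.0, 10.0, 10.0, 10.0])
    exch = np.concatenate([rng.uniform(0.4, 4.0, size=5), [1.0]])
    return GTRIGParams(
        base_freqs=freqs,
        exchangeabilities=exch,
        gamma_shape=float(rng.uniform(0.3, 2.0)),
        p_inv=float(rng.uniform(0.05, 0.4)) if with_inv else 0.0,
        n_categories=k,
    )
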