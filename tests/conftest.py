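import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loewe2d import BiphasicModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def zn_model() -> BiphasicModel:
    """Log-Gaussian parameter set for the Zn biosensor response (derived from
    its published two-dimensional effective-dose vectors)."""
    return BiphasicModel("loggaussian", b=0.4103, c=2.27, d=79.31, e=2.43, f=0.66)


@pytest.fixture
def simple_gaussian() -> BiphasicModel:
    return BiphasicModel("gaussian", b=1.0, c=0.0, d=10.0, e=5.0, f=1.0)


def random_model(rng: np.random.Generator) -> BiphasicModel:
    """Draw a random valid biphasic model.

    Gaussian peak locations are kept at least 3.5 left-widths above zero so
    every dose on the p in [-99, 99] range stays positive.
    """
    kind = rng.choice(["gaussian", "loggaussian"])
    b = rng.uniform(0.1, 1.5)
    c = rng.uniform(0.0, 5.0)
    d = c + rng.uniform(5.0, 100.0)
    f = rng.uniform(0.3, 3.0)
    if kind == "gaussian":
        e = 3.5 * b * 3.1 * rng.uniform(1.0, 3.0)
    else:
        e = rng.uniform(0.5, 20.0)
    return BiphasicModel(kind, b=b, c=c, d=d, e=e, f=f)
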