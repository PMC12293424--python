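import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alpsim import PhantomSpec, build_gradient_scheme, build_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_phantom_spec(**kw) -> PhantomSpec:
    """A reduced grid that still contains both fiber blocks and all nine ROI
    pairs: 16 x 16 x 8 voxels at 2 mm."""
    kw.setdefault("shape", (16, 16, 8))
    kw.setdefault("origin", (-48.0, -40.0, 20.0))
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def shell800_scheme():
    """Single b=800 shell, 30 directions + 2 b=0 volumes."""
    return build_gradient_scheme(30, [800.0], n_b0=2, seed=11)


@pytest.fixture(scope="session")
def two_shell_scheme():
    """The full acquisition layout: 8 b=0 + 30 @ b=800 + 30 @ b=2800."""
    return build_gradient_scheme(30, [800.0, 2800.0], n_b0=8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
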