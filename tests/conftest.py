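import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    from clasifish import default_panel

    return default_panel()


@pytest.fixture(scope="session")
def spectra(panel):
    from clasifish import synthetic_reference_spectra

    return synthetic_reference_spectra(panel.dye_list)


@pytest.fixture(scope="session")
def small_tip_fixture():
    """One rendered 256-px tip-preset scene shared across tests."""
    from clasifish import make_fixtures

    return make_fixtures("tip", seed=11, px=256)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
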