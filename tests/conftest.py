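import pytest

from cugel.config import default_config
from cugel.pipeline import run_sweep
from cugel.units import ReleaseSpec


@pytest.fixture(scope="session")
def cfg():
    """Packaged default configuration (calibrated, frozen)."""
    return default_config()


@pytest.fixture(scope="session")
def release():
    """Reference corrosion source: 50 ug/day over 200 mm2."""
    return ReleaseSpec(daily_release=50.0, copper_area=2.0e-4)


@pytest.fixture(scope="session")
def default_sweep(cfg):
    """The full 20-row material x pH x thickness dose sweep."""
    return run_sweep(cfg)
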