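import pytest
from hypothesis import settings

from mesogm import PhotoParams, ResistanceParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def photo():
    """Reference biochemistry: ambient O2, Gamma* ~= 34 ubar."""
    return PhotoParams(Vcmax=80.0, J=125.0, Rd=1.0, KmC=291.0, KmO=194.0, Sco=3.1)


@pytest.fixture
def make_resistance():
    """Factory for the reference diffusion network (gm_dif = 0.4)."""

    def _make(omega=0.5, sigma=0.5, **kw):
        return ResistanceParams(gm_dif=0.4, omega=omega, sigma=sigma, **kw)

    return _make
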