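import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "osmosim",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("osmosim")

import osmosim as om  # noqa: E402


@pytest.fixture(scope="session")
def calibrated():
    """(params, initial state) for the default 74-kg subject."""
    return om.calibrate()


@pytest.fixture(scope="session")
def params(calibrated):
    return calibrated[0]


@pytest.fixture(scope="session")
def baseline():
    return om.find_baseline()


@pytest.fixture(scope="session")
def run_a():
    """Protocol A (acute water load) at the default fine step."""
    return om.integrate(om.build_protocol("A"), dt=0.05)


@pytest.fixture(scope="session")
def run_a_coarse():
    """Protocol A at twice the step of ``run_a`` (dt-refinement checks)."""
    return om.integrate(om.build_protocol("A"), dt=0.1)


@pytest.fixture(scope="session")
def long_runs():
    """Protocols B-F integrated at a coarse but stable 0.5-min step."""
    return {pid: om.integrate(om.build_protocol(pid), dt=0.5)
            for pid in ("B", "C", "D", "E", "F")}
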