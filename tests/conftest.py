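import pytest
from hypothesis import HealthCheck, settings

from oxyloop.controller import ControllerConfig, DEFAULT_MH, DEFAULT_SH
from oxyloop.physiology import PatientParams
from oxyloop.sensor import OximeterSample, SensorParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config() -> ControllerConfig:
    return ControllerConfig()


@pytest.fixture
def sh():
    return DEFAULT_SH


@pytest.fixture
def mh():
    return DEFAULT_MH


@pytest.fixture
def moderate_params() -> PatientParams:
    return PatientParams(shunt_fraction=0.12)


@pytest.fixture
def severe_params() -> PatientParams:
    return PatientParams(shunt_fraction=0.25)


@pytest.fixture
def quiet_sensor() -> SensorParams:
    """Noiseless sensor with no dropout/low-SIQ events."""
    return SensorParams(noise_sd=0.0, dropout_rate=0.0, low_siq_rate=0.0)


def make_sample(
    t: float = 0.0,
    spo2: "int | None" = 94,
    siq: float = 0.98,
    signal_present: bool = True,
) -> OximeterSample:
    return OximeterSample(t=t, spo2=spo2, hr=80.0, pi=2.0, siq=siq, signal_present=signal_present)


@pytest.fixture
def sample_factory():
    return make_sample
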