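import pytest
from hypothesis import HealthCheck, settings

import microtherm as mt

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reference_rig():
    """The calibrated reference rig: plant, noiseless sensor, controller, protocol."""
    return mt.reference_config()


@pytest.fixture(scope="session")
def reference_run(reference_rig):
    """One noiseless reference experiment (stages 40/42/44 °C), shared read-only."""
    plant, sensor, ctrl, proto = reference_rig
    trace, relay = mt.run_experiment(proto, plant, sensor, ctrl)
    return trace, relay
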