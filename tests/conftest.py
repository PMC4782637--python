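import numpy as np
import pytest

import cinegate as cg


@pytest.fixture(scope="session")
def regular_ecg():
    """Metronomic heart: RR exactly 150 ms for 30 s."""
    return cg.simulate_ecg(30.0, 0.15, 0.0, seed=0)


@pytest.fixture(scope="session")
def jittered_ecg():
    """Irregular heart: RR 143 ms with 8 ms beat-to-beat jitter, 200 s."""
    return cg.simulate_ecg(200.0, 0.143, 0.008, seed=3)


@pytest.fixture(scope="session")
def free_resp():
    """Free-running ventilation at 60 breaths/min for 200 s."""
    return cg.simulate_ventilated_respiration(200.0, 60.0, 0.4)


@pytest.fixture(scope="session")
def held_resp():
    """Ventilation with a 7 s end-expiratory breath hold starting at 2 s."""
    return cg.simulate_ventilated_respiration(20.0, 60.0, 0.4, breath_holds=((2.0, 9.0),))


@pytest.fixture(scope="session")
def kidney_scene():
    return cg.KidneyScene(grid=64)


@pytest.fixture(scope="session")
def dsa_stack(held_resp, kidney_scene):
    """A complete noiseless kidney DSA run: 40 frames, 6 pre-contrast."""
    ecg = cg.simulate_ecg(20.0, 0.15, 0.0, seed=0)
    return cg.run_dsa_protocol(
        cg.DsaProtocol(), ecg.trigger_train(), held_resp, kidney_scene
    )
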