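import numpy as np
import pytest

from vmatrl.dose import KernelParams, precompute_beamlets
from vmatrl.machine import MachineModel, build_arc_template
from vmatrl.phantoms import generate_phantom


@pytest.fixture(scope="session")
def toy_machine():
    # field half-width trimmed to the toy grid span; CP interval scaled with
    # the 15 degree toy spacing
    return MachineModel(field_half_width=6.5, cp_delivery_time=3.75)


@pytest.fixture(scope="session")
def toy_arc():
    return build_arc_template(15.0, gap=None)  # 24 CPs


@pytest.fixture(scope="session")
def toy_phantom():
    return generate_phantom(1, "toy")


@pytest.fixture(scope="session")
def toy_bank(toy_phantom, toy_arc, toy_machine):
    return precompute_beamlets(toy_phantom, toy_arc, toy_machine)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
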