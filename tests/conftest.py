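import numpy as np
import pytest

from pbsbeam import synth
from pbsbeam.materials import build_material_table


@pytest.fixture(scope="session")
def preset():
    return synth.PROVISION


@pytest.fixture(scope="session")
def machine(preset):
    """Commissioned machine model (fitted once per session)."""
    return preset.machine_model()


@pytest.fixture(scope="session")
def mat_table():
    return build_material_table()


@pytest.fixture(scope="session")
def water_box():
    return synth.gen_phantom("water_box", dims=(12.0, 12.0, 22.0),
                             voxel=(0.3, 0.3, 0.2), entry_z=-15.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
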