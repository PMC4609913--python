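import numpy as np
import pytest

from autoloop import model_core as mc


@pytest.fixture(scope="session")
def default_system():
    return mc.default_system()


@pytest.fixture(scope="session")
def default_trajectory(default_system):
    return mc.simulate(default_system)


@pytest.fixture
def single_ligand():
    """Factory for a one-ligand system with overridable ligand fields."""

    def make(**ligand_kwargs):
        lig = {"name": "L", "kd_nM": 1.0, "release_rate": 10.0}
        lig.update(ligand_kwargs)
        return mc.build_system({"ligands": [lig]})

    return make
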