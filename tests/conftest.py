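import numpy as np
import pytest

from msdesign.energy import ToyEnergyParams
from msdesign.structure import Residue, Structure
from msdesign.synthetic import generate_synthetic_system


@pytest.fixture(scope="session")
def params():
    return ToyEnergyParams()


@pytest.fixture(scope="session")
def het_system():
    """Small heterodimerization system shared across tests."""
    return generate_synthetic_system("heterodimer_task", 4, seed=11)


@pytest.fixture()
def line_structure():
    """Five residues on a line, frames pointing +z."""
    frame = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    residues = [
        Residue("A", i + 1, aa, np.array([3.5 * i, 0.0, 0.0]), frame)
        for i, aa in enumerate("FALAG")
    ]
    return Structure(residues, name="line")


def make_rotamer(radius=1.2, h=0.0, center=(0.0, 0.0, 0.0), aa="A", ori=0):
    from msdesign.energy import Rotamer
    return Rotamer(aa, ori, np.asarray(center, float), radius, h)
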