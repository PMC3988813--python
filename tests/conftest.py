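import numpy as np
import pytest

from nanoconfine.potential import PotentialConfig
from nanoconfine.sas import compute_sas
from nanoconfine.structures import ParameterTable, build_planar_slab
from nanoconfine.supercooled_thermo import ThermoTables


@pytest.fixture(scope="session")
def table():
    """Generic silica-like parameter table (kJ/mol, nm, e)."""
    return ParameterTable(
        {
            "Si": (2.5, 0.35, -0.3),
            "O": (0.65, 0.32, 0.15),
            "X": (1.0, 0.30, 0.0),
        }
    )


@pytest.fixture(scope="session")
def neutral_table():
    return ParameterTable({"Si": (2.5, 0.35, 0.0), "X": (1.0, 0.30, 0.0)})


@pytest.fixture(scope="session")
def slab(table):
    """Small charged slab: 2 layers, laterally periodic."""
    return build_planar_slab(2.0, 2, 0.3, "Si", table)


@pytest.fixture(scope="session")
def slab_sas(slab):
    return compute_sas(slab)


@pytest.fixture(scope="session")
def config():
    return PotentialConfig()


@pytest.fixture(scope="session")
def const_cp_tables():
    """Constant c_p and a tabulated exponential diffusivity ratio.

    The closed-form composition T* = T0 - eps/c_p makes this the oracle
    fixture for the supercooled-water chain.
    """
    T = np.linspace(150.0, 320.0, 200)
    cp = 4186.0
    g = np.clip(np.exp((T - 300.0) / 40.0), 0.0, 1.0)
    return ThermoTables(
        cp_samples=[(t, cp) for t in T],
        g_samples=[(t, r) for t, r in zip(T, g)],
        T0=300.0,
    )
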