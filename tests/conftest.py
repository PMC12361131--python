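import numpy as np
import pytest

import fieldmorph as fm


@pytest.fixture(scope="session")
def pc_neuron():
    """One active PC L2/3 cell, default biophysics."""
    return fm.generate_neuron(fm.default_class_spec("PC", "L23"), fm.default_biophysics(), 11)


@pytest.fixture(scope="session")
def pv_neuron():
    return fm.generate_neuron(fm.default_class_spec("PV", "L4"), fm.default_biophysics(), 12)


@pytest.fixture(scope="session")
def passive_cable():
    """Passive straight vertical cable, 1000 µm × 1 µm, 10 µm compartments."""
    return fm.straight_cable_neuron(1000.0, 1.0, soma_radius=0.5,
                                    max_compartment_length=10.0)


@pytest.fixture(scope="session")
def default_population():
    """The default 27-cell layout with active biophysics (no simulation)."""
    return fm.generate_population(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
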