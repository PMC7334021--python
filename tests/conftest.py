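import numpy as np
import pytest

import ttl5sim as t5
from ttl5sim.model import build_reduced


@pytest.fixture(scope="session")
def default_spec():
    return build_reduced(600.0)


@pytest.fixture(scope="session")
def default_disc(default_spec):
    return default_spec.discretize()


@pytest.fixture(scope="session")
def short_spec():
    return build_reduced(200.0)


@pytest.fixture()
def passive_comp():
    """Single passive compartment: R_m = 10 kΩ·cm², C_m = 1 -> tau 10 ms."""
    sec = t5.SectionSpec("soma", length=20.0, diameter=20.0,
                         leak_conductance=0.1, leak_reversal=-65.0,
                         n_compartments=1)
    return t5.discretize([sec])


def sealed_cable(n_compartments=200, diameter=2.0, rm_kohm=15.0, ra=100.0):
    """Uniform passive cable of physical length exactly one length constant."""
    probe = t5.SectionSpec("c", length=1.0, diameter=diameter,
                           axial_resistivity=ra, leak_conductance=1.0 / rm_kohm)
    lam = probe.length_constant()
    sec = t5.SectionSpec("cab", length=lam, diameter=diameter,
                         axial_resistivity=ra, leak_conductance=1.0 / rm_kohm,
                         leak_reversal=-65.0, n_compartments=n_compartments)
    return t5.discretize([sec]), lam


@pytest.fixture()
def lambda_cable():
    return sealed_cable()
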