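import numpy as np
import pytest

from memtube.energy import EnergyParams
from memtube.engine import MCParams, MCState
from memtube.mesh import build_cylinder
from memtube.proteins import Protein, ProteinParams
from memtube.scenarios import place_proteins


@pytest.fixture(scope="session")
def small_tube():
    """A ~270-bead tube: big enough for every move kind, fast to sweep."""
    return build_cylinder(4.0, 16.0, seed=11)


@pytest.fixture(scope="session")
def paper_tube():
    """The study-sized tube: radius 10 sigma, length 100 sigma."""
    return build_cylinder(10.0, 100.0, seed=7)


def _state(mesh, n_proteins=2, seed=5, **mc_kwargs):
    ep = EnergyParams()
    pp = ProteinParams()
    rng = np.random.default_rng(seed)
    prots = place_proteins(mesh.nominal_radius, mesh.box_length, n_proteins,
                           pp, ep, rng)
    return MCState(mesh.copy(), prots, ep, pp,
                   MCParams(seed=seed, **mc_kwargs))


@pytest.fixture
def small_state(small_tube):
    """Tube + 2 proteins, fresh per test (sweeps mutate it)."""
    return _state(small_tube, n_proteins=2, seed=5)


@pytest.fixture(scope="session")
def thermalised_state(small_tube):
    """A short-equilibrated system shared by read-only tests."""
    st = _state(small_tube, n_proteins=2, seed=9)
    st.sweep(30)
    return st
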