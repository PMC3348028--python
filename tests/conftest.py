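import numpy as np
import pytest

from mbg import fixtures as fx
from mbg.geometry import RigidTransform
from mbg.sse import MotifDescriptor, detect_sses, fit_line_vector
from mbg.structures import Structure


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def domain_structure():
    """Compact asymmetric helix-strand-helix domain (pseudo-backbone)."""
    chain = fx._chain_from_ca(fx.make_domain(seed=0), "A", 1)
    return Structure(id="domain", chains=[chain])


@pytest.fixture
def domain_motif(domain_structure):
    vecs = [fit_line_vector(s) for s in detect_sses(domain_structure)]
    assert len(vecs) == 3
    return MotifDescriptor(vecs, "domain")


@pytest.fixture
def two_chain_structure():
    """Two well-separated chains: an A helix and a B strand."""
    a = fx.make_ideal_helix(6, chain_id="A")
    b = fx.make_ideal_strand(5, chain_id="B")
    shift = np.array([40.0, 0.0, 0.0])
    for atom in b.atoms():
        atom.coords = atom.coords + shift
    return Structure(id="two_chain", chains=a.chains + b.chains)


def random_rigid_transform(rng, max_angle_deg=180.0, max_translation=10.0):
    axis = rng.normal(size=3)
    angle = rng.uniform(0.0, np.radians(max_angle_deg))
    t = rng.uniform(-1.0, 1.0, size=3) * max_translation
    return RigidTransform.from_axis_angle(axis, angle, translation=t)
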