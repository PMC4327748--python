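import numpy as np
import pytest

from ssassign.fixtures import (
    make_alpha_helix,
    make_antiparallel_hairpin,
    make_extended_strand,
)
from ssassign.pdbio import Atom, Chain, Residue, Structure


@pytest.fixture
def helix12():
    return make_alpha_helix(12)


@pytest.fixture
def strand6():
    return make_extended_strand(6)


@pytest.fixture
def hairpin5():
    return make_antiparallel_hairpin(5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def synthetic_chain(ca_positions, o_directions=None, chain_id="A"):
    """Structure with residues at given CA positions and locally consistent
    N/C placement so that no chain breaks are detected."""
    ca_positions = [np.asarray(p, dtype=float) for p in ca_positions]
    chain = Chain(chain_id)
    for i, ca in enumerate(ca_positions):
        res = Residue(chain_id=chain_id, res_seq=i + 1, i_code=" ", res_name="ALA")
        n = ca + np.array([-0.5, 0.0, 0.0])
        c = ca + np.array([0.5, 0.0, 0.0])
        if o_directions is not None:
            o = c + 1.23 * np.asarray(o_directions[i], dtype=float)
        else:
            o = c + np.array([0.0, 1.23, 0.0])
        for k, (name, pos) in enumerate([("N", n), ("CA", ca), ("C", c), ("O", o)]):
            res.atoms[name] = Atom(4 * i + k + 1, name, " ", name[0], pos)
        chain.residues.append(res)
    return Structure(chains=[chain])


def random_walk_cas(rng, n, step=1.5, jitter=0.5):
    """CA trace whose spacing keeps the synthetic chain unbroken."""
    cas = [np.zeros(3)]
    for _ in range(n - 1):
        cas.append(cas[-1] + np.array([step, 0.0, 0.0]) + rng.uniform(-jitter, jitter, 3))
    return cas
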