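import numpy as np
import pytest

from ribogate.geometry import default_registry
from ribogate.structures import Atom, Residue, Structure
from ribogate.synthetic import HelixSpec, make_d1_construct, make_helix

# hand-written 3-residue, 9-atom PDB fixture
TINY_PDB = """\
ATOM      1  P     G A   1       1.000   2.000   3.000  1.00 10.00           P
ATOM      2  C1'   G A   1       2.000   2.500   3.500  1.00 10.00           C
ATOM      3  N9    G A   1       3.000   3.000   4.000  1.00 10.00           N
ATOM      4  P     C A   2       4.000   5.000   6.000  1.00 11.00           P
ATOM      5  C1'   C A   2       5.000   5.500   6.500  1.00 11.00           C
ATOM      6  N1    C A   2       6.000   6.000   7.000  1.00 11.00           N
ATOM      7  P     U A   3       7.000   8.000   9.000  1.00 12.00           P
ATOM      8  C1'   U A   3       8.000   8.500   9.500  1.00 12.00           C
ATOM      9  N1    U A   3       9.000   9.000  10.000  1.00 12.00           N
END
"""


@pytest.fixture()
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def ideal_helix():
    """Noiseless 12-bp duplex along +z, both strands on chain A."""
    return make_helix(HelixSpec(n_bp=12, chain_ids=("A", "A"), start_seq_nums=(1, 101)))


@pytest.fixture(scope="session")
def d1_construct():
    """Noiseless four-helix scaffold mimic with ground-truth descriptors."""
    return make_d1_construct(angle_a=62.9, angle_b=30.0, angle_c=45.0, angle_d=60.0,
                             gate_dist=32.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_chain_structure(n_res: int = 300, chain: str = "A") -> Structure:
    """n_res-nucleotide single chain with P/C4'/C1' atoms at distinct points."""
    residues = []
    for i in range(n_res):
        r = Residue(chain_id=chain, seq_num=i + 1, res_name="A")
        base = np.array([np.cos(0.4 * i), np.sin(0.4 * i), 0.5 * i])
        r.add_atom(Atom("P", "P", base))
        r.add_atom(Atom("C4'", "C", base + [0.5, 0.2, 0.1]))
        r.add_atom(Atom("C1'", "C", base + [1.0, -0.3, 0.2]))
        residues.append(r)
    return Structure(id="chain300", residues=residues)
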