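import numpy as np
import pytest

from rdcfit.core import PairType, RDCDatum, RDCSet, make_vector
from rdcfit.synthetic import MEDIUM_TENSORS, make_vectors, simulate_rdc


@pytest.fixture
def m1():
    """Diagonal reference tensor, principal values (-3, -5, 8) x 1e-4."""
    return MEDIUM_TENSORS["M1"]


@pytest.fixture
def m2():
    """Rotated reference tensor, principal values (2, 5, -7) x 1e-4 at ZYZ
    Euler angles (-40, -50, 60) degrees."""
    return MEDIUM_TENSORS["M2"]


@pytest.fixture
def fib20():
    return make_vectors(20, scheme="fibonacci")


@pytest.fixture
def clean_m1_set(m1, fib20):
    """Noise-free couplings from M1 on 20 quasi-uniform vectors."""
    return simulate_rdc(m1, fib20, pair="N-H", noise=None, seed=0)


#: unit-scale pair for examples stated in terms of dmax/r^3 = 1e4 Hz
UNIT_PAIR = PairType(name="unit", gamma_i=1.0, gamma_j=1.0, dmax_unit=1.0e4)


def unit_datum(direction, d_obs=0.0, error=0.0, index=1):
    """Datum with dmax/r^3 = 1e4 Hz along a given direction."""
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    return RDCDatum(
        vector=make_vector((0.0, 0.0, 0.0), tuple(v)),
        d_obs=d_obs, error=error, dmax=UNIT_PAIR.dmax_unit, index=index,
    )


def _pdb_atom(serial, name, resname, resseq, xyz, occ=1.0, altloc=" ", chain="A"):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
    )


def make_pdb_text(n_residues=3, omit_first_h=False):
    """Synthetic extended-chain peptide PDB text for extraction tests."""
    lines = []
    serial = 1
    for i in range(n_residues):
        x0 = 3.8 * i
        atoms = [
            ("N", (x0, 0.0, 0.0)),
            ("H", (x0, 0.0, 1.02)),
            ("CA", (x0 + 1.45, 0.0, 0.0)),
            ("HA", (x0 + 1.45, 1.09, 0.0)),
            ("C", (x0 + 2.97, 0.0, 0.0)),
        ]
        for name, xyz in atoms:
            if omit_first_h and i == 0 and name == "H":
                continue
            lines.append(_pdb_atom(serial, name, "ALA", i + 1, xyz))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(make_pdb_text())
    return path
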