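import math

import numpy as np
import pytest

from hitfunnel import bundled_hit_table
from hitfunnel.synthetic_data import gen_toy_conformers

# idealized backbone geometry (Å / degrees) for building test peptides
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7


def place_atom(a, b, c, r, theta_deg, torsion_deg):
    """NeRF placement: position d with bond r to c, angle d-c-b, torsion d-c-b-a."""
    theta = math.radians(theta_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta), r * math.sin(theta) * math.cos(tor),
                  r * math.sin(theta) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi_list, omega=180.0):
    """Backbone (N, CA, C per residue) realizing the given (phi, psi) list.

    phi of the first residue and psi of the last are unused (terminal).
    Returns a list of (residue_index, residue_name, {atom: xyz}).
    """
    n_res = len(phi_psi_list)
    N1 = np.array([0.0, 0.0, 0.0])
    CA1 = np.array([BOND_N_CA, 0.0, 0.0])
    th = math.radians(ANGLE_N_CA_C)
    C1 = CA1 + np.array([-BOND_CA_C * math.cos(th), BOND_CA_C * math.sin(th), 0.0])
    atoms = [{"N": N1, "CA": CA1, "C": C1}]
    for i in range(1, n_res):
        prev = atoms[-1]
        psi_prev = phi_psi_list[i - 1][1]
        N = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA = place_atom(prev["CA"], prev["C"], N, BOND_N_CA, ANGLE_C_N_CA, omega)
        C = place_atom(prev["C"], N, CA, BOND_CA_C, ANGLE_N_CA_C, phi_psi_list[i][0])
        atoms.append({"N": N, "CA": CA, "C": C})
    return [(i + 1, "ALA", at) for i, at in enumerate(atoms)]


def write_backbone_pdb(residues, path):
    with open(path, "w") as fh:
        serial = 1
        for ridx, rname, at in residues:
            for name in ("N", "CA", "C"):
                x, y, z = at[name]
                el = name[0]
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{rname:>3s} A{ridx:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


@pytest.fixture(scope="session")
def hit_table():
    return bundled_hit_table()


@pytest.fixture(scope="session")
def rgz_conformer():
    ref, _, _ = gen_toy_conformers("rgz_like")
    return ref


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
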