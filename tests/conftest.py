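"""Shared fixtures and geometry helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pilusmech.structure_core import AtomRecord, StructureModel

# standard backbone geometry for building chains with exact dihedrals
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with given C-D bond, B-C-D angle and
    A-B-C-D torsion."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg - 180.0)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + bond * (-np.cos(ang) * bc
                       + np.sin(ang) * (np.cos(tor) * m + np.sin(tor) * n))


def build_backbone(phi_psi: list[tuple[float, float]], chain_id: str = "A",
                   res_name: str = "ALA", start_res: int = 1) -> StructureModel:
    """Backbone-only chain (N, CA, C per residue) with exact phi/psi.

    phi of the first residue and psi of the last are ignored; omega is 180.
    """
    n_res = len(phi_psi)
    coords: list[tuple[str, np.ndarray]] = []
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c1 = ca1 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords += [("N", n1), ("CA", ca1), ("C", c1)]
    for r in range(1, n_res):
        psi_prev = phi_psi[r - 1][1]
        phi = phi_psi[r][0]
        n_prev, ca_prev, c_prev = (coords[-3][1], coords[-2][1], coords[-1][1])
        n_new = _place(n_prev, ca_prev, c_prev, _BOND_C_N,
                       _ANGLE_CA_C_N, psi_prev)
        ca_new = _place(ca_prev, c_prev, n_new, _BOND_N_CA,
                        _ANGLE_C_N_CA, 180.0)
        c_new = _place(c_prev, n_new, ca_new, _BOND_CA_C,
                       _ANGLE_N_CA_C, phi)
        coords += [("N", n_new), ("CA", ca_new), ("C", c_new)]
    atoms = []
    for i, (name, pos) in enumerate(coords):
        atoms.append(AtomRecord(
            serial=i + 1, name=name, element=name[0], alt_loc="",
            res_name=res_name, chain_id=chain_id,
            res_seq=start_res + i // 3, position=pos))
    return StructureModel(atoms=atoms, label="built_chain")


def dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1, v), w),
                                       np.dot(v, w))))


def sphere_model(centers, radii, chain_id: str = "A") -> StructureModel:
    """Model of bare spheres with explicit radii (element C)."""
    atoms = []
    for i, (center, radius) in enumerate(zip(centers, radii)):
        atoms.append(AtomRecord(
            serial=i + 1, name="CA", element="C", alt_loc="",
            res_name="SPH", chain_id=chain_id, res_seq=i + 1,
            position=np.asarray(center, dtype=float), vdw_radius=float(radius)))
    return StructureModel(atoms=atoms, label="spheres")


@pytest.fixture
def one_atom_pdb(tmp_path):
    path = tmp_path / "one_atom.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00  0.00"
        "           C\n"
        "END\n")
    return path


MINIMAL_MMCIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 ? 0.000 1.000 2.000 1.00 0.00 5 ALA B N 1
ATOM 2 C CA . ALA A 1 1 ? 1.458 1.000 2.000 1.00 0.00 5 ALA B CA 1
ATOM 3 C C . ALA A 1 1 ? 2.009 2.420 2.000 1.00 0.00 5 ALA B C 1
HETATM 4 O O . HOH A 1 2 ? 8.000 8.000 8.000 1.00 0.00 101 HOH B O 1
"""


@pytest.fixture
def minimal_mmcif(tmp_path):
    path = tmp_path / "minimal.cif"
    path.write_text(MINIMAL_MMCIF)
    return path
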