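"""Solvent-accessible surface area, buried interface areas per neighbor
offset, cross-subunit salt bridges, and dihedral-based helix segmentation.

SASA follows Shrake-Rupley with a deterministic Fibonacci-lattice point set,
so results are exactly reproducible. Buried interface area uses the halved
difference (SASA(A) + SASA(B) - SASA(AB)) / 2 — the convention under which
published per-interface areas are reported — with the unhalved difference
also returned for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from pilusmech.helix_builder import FilamentModel
from pilusmech.structure_core import StructureModel

__all__ = [
    "SasaResult",
    "InterfaceReport",
    "InterfaceSummary",
    "HelixSegmentation",
    "SaltBridge",
    "compute_sasa",
    "buried_interface_area",
    "enumerate_interfaces",
    "find_salt_bridges",
    "segment_helices",
]

# side-chain atoms carrying formal charge, for salt-bridge detection
_BASIC_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class SasaResult:
    per_atom: np.ndarray
    per_residue: dict[tuple[str, int, str], float]
    total: float
    probe_radius: float
    n_points: int


@dataclass
class SaltBridge:
    basic_residue: tuple[str, int, str]   # (chain, res_seq, res_name)
    acidic_residue: tuple[str, int, str]
    distance: float


@dataclass
class InterfaceReport:
    offset_k: int
    buried_area: float            # halved (per-interface) convention, Å²
    buried_area_full: float       # unhalved SASA difference, Å²
    residue_pairs: list[tuple[tuple[str, int, str], tuple[str, int, str], float]]
    salt_bridges: list[SaltBridge] = field(default_factory=list)


@dataclass
class InterfaceSummary:
    interfaces: list[InterfaceReport]
    total_per_subunit: float
    total_per_pilin: float
    n_partners: int
    min_area: float

    @classmethod
    def from_reports(cls, reports: list[InterfaceReport],
                     min_area: float = 10.0) -> "InterfaceSummary":
        kept = sorted((r for r in reports if r.buried_area >= min_area),
                      key=lambda r: -r.buried_area)
        total = sum(r.buried_area for r in kept)
        return cls(interfaces=kept, total_per_subunit=total,
                   total_per_pilin=2.0 * total, n_partners=2 * len(kept),
                   min_area=min_area)


@dataclass
class HelixSegmentation:
    segments: list[tuple[int, int, str]]   # (start res_seq, end res_seq, class)
    alpha1N: tuple[int, int] | None
    melted: tuple[int, int] | None
    alpha1C: tuple[int, int] | None


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(model: StructureModel, probe: float = 1.4,
                 n_points: int = 960, method: str = "grid") -> SasaResult:
    """Shrake-Rupley SASA with a fixed Fibonacci point set.

    `method="grid"` prunes neighbor candidates with a KD-tree; `"brute"`
    tests every atom pair. Both give bitwise-identical areas.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    if len(model) == 0:
        raise ValueError("empty model")
    coords = model.coords
    radii = model.radii  # raises naming unassigned atoms
    inflated = radii + probe
    sphere = fibonacci_sphere(n_points)
    n = len(model)
    per_atom = np.zeros(n)

    if method == "brute":
        neighbor_lists = [
            [j for j in range(n) if j != i
             and np.linalg.norm(coords[i] - coords[j]) < inflated[i] + inflated[j]]
            for i in range(n)
        ]
    elif method == "grid":
        tree = cKDTree(coords)
        max_cut = 2.0 * inflated.max()
        pairs = tree.query_pairs(max_cut, output_type="ndarray")
        neighbor_lists: list[list[int]] = [[] for _ in range(n)]
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            keep = d < inflated[pairs[:, 0]] + inflated[pairs[:, 1]]
            for i, j in pairs[keep]:
                neighbor_lists[i].append(j)
                neighbor_lists[j].append(i)
    else:
        raise ValueError("method must be 'grid' or 'brute'")

    for i in range(n):
        points = coords[i] + inflated[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in sorted(neighbor_lists[i]):
            d2 = np.einsum("ij,ij->i", points - coords[j], points - coords[j])
            accessible &= d2 >= inflated[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * inflated[i] ** 2

    per_residue: dict[tuple[str, int, str], float] = {}
    for atom, area in zip(model.atoms, per_atom):
        key = (atom.chain_id, atom.res_seq, atom.i_code)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      total=float(per_atom.sum()), probe_radius=probe,
                      n_points=n_points)


# ---------------------------------------------------------------------------
# Interfaces
# ---------------------------------------------------------------------------

def _merge(a: StructureModel, b: StructureModel) -> StructureModel:
    return StructureModel(atoms=[x.copy() for x in a.atoms] +
                          [x.copy() for x in b.atoms], label="pair")


def _contact_pairs(a: StructureModel, b: StructureModel, cutoff: float,
                   ) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Residue pairs across the a/b divide with min heavy-atom distance <= cutoff."""
    ca, cb = a.coords, b.coords
    tree_b = cKDTree(cb)
    pairs: dict[tuple, float] = {}
    hits = tree_b.query_ball_point(ca, cutoff)
    for i, js in enumerate(hits):
        if not js:
            continue
        atom_a = a.atoms[i]
        key_a = (atom_a.chain_id, atom_a.res_seq, atom_a.res_name)
        for j in js:
            atom_b = b.atoms[j]
            key_b = (atom_b.chain_id, atom_b.res_seq, atom_b.res_name)
            d = float(np.linalg.norm(ca[i] - cb[j]))
            key = (key_a, key_b)
            if key not in pairs or d < pairs[key]:
                pairs[key] = d
    return sorted(((ka, kb, d) for (ka, kb), d in pairs.items()),
                  key=lambda t: t[2])


def buried_interface_area(filament: FilamentModel, offset_k: int,
                          probe: float = 1.4, n_points: int = 960,
                          contact_cutoff: float = 4.5,
                          central: int = 0) -> InterfaceReport:
    """Pairwise buried area between subunit `central` and subunit `central - offset_k`.

    Context subunits are excluded: the two subunits are evaluated in
    isolation, matching how per-interface areas of a complex are normally
    reported. buried_area is the halved difference; buried_area_full the
    unhalved one.
    """
    if offset_k < 1:
        raise ValueError("offset_k must be >= 1")
    lower = central - offset_k
    for idx in (central, lower):
        if idx not in filament.subunits:
            raise KeyError(
                f"filament lacks subunit {idx}; build with a range spanning it")
    a = filament.subunits[central]
    b = filament.subunits[lower]
    if filament.params is not None and central != 0:
        # pose the pair in the frame of the central subunit so the fixed
        # SASA point set sees identical geometry for every central index
        from pilusmech.helix_builder import symmetry_operator
        from pilusmech.structure_core import apply_transform

        to_origin = symmetry_operator(filament.params, -central)
        a = apply_transform(a, to_origin)
        b = apply_transform(b, to_origin)
    sa = compute_sasa(a, probe, n_points).total
    sb = compute_sasa(b, probe, n_points).total
    sab = compute_sasa(_merge(a, b), probe, n_points).total
    full = sa + sb - sab
    report = InterfaceReport(
        offset_k=offset_k,
        buried_area=full / 2.0,
        buried_area_full=full,
        residue_pairs=_contact_pairs(a, b, contact_cutoff),
    )
    report.salt_bridges = find_salt_bridges(filament, offset_k, central=central)
    return report


def enumerate_interfaces(filament: FilamentModel, max_offset: int = 9,
                         min_area: float = 10.0, probe: float = 1.4,
                         n_points: int = 960,
                         central: int = 0) -> InterfaceSummary:
    """All N:N-k interfaces of the central subunit for k = 1..max_offset.

    total_per_subunit sums unique offsets passing min_area; total_per_pilin
    doubles it (each subunit also contacts the mirror partners above), and
    n_partners doubles the interface count for the same reason.
    """
    indices = filament.indices()
    need_low = central - max_offset
    if need_low not in filament.subunits or central not in filament.subunits:
        raise ValueError(
            f"filament spans {indices[0]}..{indices[-1]} but offsets through "
            f"{max_offset} about subunit {central} require down to {need_low}")
    reports = [buried_interface_area(filament, k, probe, n_points, central=central)
               for k in range(1, max_offset + 1)]
    return InterfaceSummary.from_reports(reports, min_area=min_area)


def find_salt_bridges(filament: FilamentModel, offset_k: int,
                      cutoff: float = 4.0, central: int = 0) -> list[SaltBridge]:
    """Cross-subunit (Arg/Lys/His N) - (Asp/Glu O) pairs within cutoff.

    Both directions across the interface are scanned; pairs are deduplicated
    to residues, retaining the minimum N-O distance.
    """
    a = filament.subunits[central]
    b = filament.subunits[central - offset_k]
    bridges: dict[tuple, float] = {}
    for basic_model, acidic_model in ((a, b), (b, a)):
        basic = [(atom, (atom.chain_id, atom.res_seq, atom.res_name))
                 for atom in basic_model.atoms
                 if atom.name in _BASIC_ATOMS.get(atom.res_name, ())]
        acidic = [(atom, (atom.chain_id, atom.res_seq, atom.res_name))
                  for atom in acidic_model.atoms
                  if atom.name in _ACIDIC_ATOMS.get(atom.res_name, ())]
        if not basic or not acidic:
            continue
        bp = np.stack([atom.position for atom, _ in basic])
        ap = np.stack([atom.position for atom, _ in acidic])
        dmat = np.linalg.norm(bp[:, None, :] - ap[None, :, :], axis=2)
        for i, j in zip(*np.nonzero(dmat <= cutoff)):
            key = (basic[i][1], acidic[j][1])
            d = float(dmat[i, j])
            if key not in bridges or d < bridges[key]:
                bridges[key] = d
    return sorted((SaltBridge(k[0], k[1], d) for k, d in bridges.items()),
                  key=lambda sb: sb.distance)


# ---------------------------------------------------------------------------
# Helix segmentation
# ---------------------------------------------------------------------------

def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(chain: StructureModel) -> dict[int, tuple[float | None, float | None]]:
    """Author-numbered residue -> (phi, psi); None at chain termini/breaks."""
    residues: dict[int, dict[str, np.ndarray]] = {}
    for atom in chain.atoms:
        if atom.name in ("N", "CA", "C"):
            residues.setdefault(atom.res_seq, {})[atom.name] = atom.position
    numbers = sorted(r for r, bb in residues.items()
                     if {"N", "CA", "C"} <= bb.keys())
    out: dict[int, tuple[float | None, float | None]] = {}
    for idx, r in enumerate(numbers):
        phi = psi = None
        bb = residues[r]
        if idx > 0 and numbers[idx - 1] == r - 1:
            prev = residues[r - 1]
            phi = _dihedral(prev["C"], bb["N"], bb["CA"], bb["C"])
        if idx < len(numbers) - 1 and numbers[idx + 1] == r + 1:
            nxt = residues[r + 1]
            psi = _dihedral(bb["N"], bb["CA"], bb["C"], nxt["N"])
        out[r] = (phi, psi)
    return out


def segment_helices(chain: StructureModel,
                    phi_window: tuple[float, float] = (-100.0, -30.0),
                    psi_window: tuple[float, float] = (-80.0, -5.0),
                    min_run: int = 4) -> HelixSegmentation:
    """Classify residues helix/coil by phi/psi windows (runs >= min_run).

    The first helix run is reported as alpha1N, the second as alpha1C, and
    the gap between them as the melted stretch. Numbering is author
    numbering throughout.
    """
    dihedrals = backbone_dihedrals(chain)
    if len(dihedrals) < 5:
        raise ValueError("chain has fewer than 5 residues with full backbone")
    numbers = sorted(dihedrals)
    helical = {}
    for r in numbers:
        phi, psi = dihedrals[r]
        helical[r] = (phi is not None and psi is not None
                      and phi_window[0] <= phi <= phi_window[1]
                      and psi_window[0] <= psi <= psi_window[1])
    # collapse into runs, demoting short helix runs to coil
    runs: list[tuple[int, int, str]] = []
    start = numbers[0]
    current = helical[start]
    prev = start
    for r in numbers[1:]:
        if helical[r] != current or r != prev + 1:
            runs.append((start, prev, "helix" if current else "coil"))
            start, current = r, helical[r]
        prev = r
    runs.append((start, prev, "helix" if current else "coil"))
    segments: list[tuple[int, int, str]] = []
    for s, e, cls in runs:
        if cls == "helix" and e - s + 1 < min_run:
            cls = "coil"
        if segments and segments[-1][2] == cls and segments[-1][1] + 1 == s:
            segments[-1] = (segments[-1][0], e, cls)
        else:
            segments.append((s, e, cls))
    helix_runs = [(s, e) for s, e, cls in segments if cls == "helix"]
    alpha1N = helix_runs[0] if helix_runs else None
    alpha1C = helix_runs[1] if len(helix_runs) > 1 else None
    melted = None
    if alpha1N and alpha1C:
        melted = (alpha1N[1] + 1, alpha1C[0] - 1)
    return HelixSegmentation(segments=segments, alpha1N=alpha1N,
                             melted=melted, alpha1C=alpha1C)
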