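"""Atomic-coordinate data model, PDB/mmCIF readers and writers, and rigid
geometry primitives shared by the structural analysis modules.

The data model is deliberately small: a flat list of :class:`AtomRecord`
grouped by author chain id, with author residue numbering kept authoritative
so residue ranges quoted in the literature can be used directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "RigidTransform",
    "StructureParseError",
    "StructureFormatError",
    "BONDI_RADII",
    "DEFAULT_RADIUS",
    "read_structure",
    "write_pdb",
    "assign_radii",
    "apply_transform",
]

#: Bondi (1964) van der Waals radii in Å, keyed by upper-case element symbol.
BONDI_RADII: Mapping[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: Fallback radius (Å) for elements missing from the chosen table.
DEFAULT_RADIUS = 1.8

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class StructureFormatError(ValueError):
    """Raised for unrecognized coordinate formats."""


@dataclass
class AtomRecord:
    """One atom with author-numbered residue context."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    position: np.ndarray
    occupancy: float = 1.0
    i_code: str = ""
    hetero: bool = False
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if not self.element:
            raise ValueError(f"atom {self.serial} has an empty element symbol")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


@dataclass
class StructureModel:
    """An ordered atom list with chain/residue hierarchy."""

    atoms: list[AtomRecord] = field(default_factory=list)
    label: str = ""
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        """(n_atoms,) van der Waals radii; raises if any are unassigned."""
        missing = [a.serial for a in self.atoms if a.vdw_radius is None]
        if missing:
            raise ValueError(
                f"atoms without assigned radii (serials {missing[:5]}...); "
                "run assign_radii first"
            )
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def chains(self) -> dict[str, list[tuple[int, str, str]]]:
        """Mapping chain_id -> ordered unique (res_seq, i_code, res_name)."""
        out: dict[str, list[tuple[int, str, str]]] = {}
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.i_code)
            if key in seen:
                continue
            seen.add(key)
            out.setdefault(a.chain_id, []).append((a.res_seq, a.i_code, a.res_name))
        return out

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def select_chain(self, chain_id: str) -> "StructureModel":
        atoms = [a.copy() for a in self.atoms if a.chain_id == chain_id]
        if not atoms:
            raise KeyError(f"no chain {chain_id!r} in model {self.label!r}")
        return StructureModel(atoms=atoms, label=f"{self.label}:{chain_id}",
                              provenance=self.provenance)

    def copy(self) -> "StructureModel":
        return StructureModel(atoms=[a.copy() for a in self.atoms],
                              label=self.label, provenance=self.provenance)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        model = self.copy()
        for atom, xyz in zip(model.atoms, coords):
            atom.position = np.asarray(xyz, dtype=float)
        return model


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        if rot.shape != (3, 3) or tra.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
            raise ValueError("rotation matrix determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then `self`."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    # fall back to content sniffing
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("data_", "loop_", "_atom_site")):
                return "mmcif"
            if stripped[:6].rstrip() in {"ATOM", "HETATM", "HEADER", "REMARK",
                                         "CRYST1", "MODEL", "TITLE"}:
                return "pdb"
    raise StructureFormatError(f"cannot determine coordinate format of {path}")


def read_structure(path: str | Path, format: str = "auto",
                   include_waters: bool = False) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Waters are excluded by default. Radii are *not* assigned here; call
    :func:`assign_radii` before any surface-area computation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "pdb":
        atoms = _read_pdb(path)
    elif format == "mmcif":
        atoms = _read_mmcif(path)
    else:
        raise StructureFormatError(f"unknown format {format!r}")
    if not include_waters:
        atoms = [a for a in atoms if a.res_name not in _WATER_NAMES]
    return StructureModel(atoms=atoms, label=path.stem,
                          provenance=f"{path}:{format}")


def _read_pdb(path: Path) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record not in ("ATOM  ", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                alt_loc = line[16].strip()
                res_name = line[17:20].strip()
                chain_id = line[21].strip()
                res_seq = int(line[22:26])
                i_code = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_field = line[54:60].strip()
                occupancy = float(occ_field) if occ_field else 1.0
                element = line[76:78].strip().upper()
            except (ValueError, IndexError) as exc:
                raise StructureParseError(
                    f"{path}:{lineno}: malformed {record.strip()} record: {exc}"
                ) from exc
            if not element:
                element = _element_from_name(name)
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element, alt_loc=alt_loc,
                res_name=res_name, chain_id=chain_id, res_seq=res_seq,
                position=np.array([x, y, z]), occupancy=occupancy,
                i_code=i_code, hetero=(record == "HETATM"),
            ))
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return atoms


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in BONDI_RADII:
        return stripped[:2].upper()
    return stripped[:1].upper()


def _read_mmcif(path: Path) -> list[AtomRecord]:
    import biotite.structure.io.pdbx as pdbx

    try:
        cif = pdbx.CIFFile.read(str(path))
        arr = pdbx.get_structure(
            cif, model=1, extra_fields=["atom_id", "occupancy"],
            use_author_fields=True,
        )
    except Exception as exc:  # biotite raises a mix of exception types
        raise StructureParseError(f"{path}: mmCIF parse failed: {exc}") from exc
    atoms: list[AtomRecord] = []
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * arr.array_length()
    for i in range(arr.array_length()):
        atoms.append(AtomRecord(
            serial=int(arr.atom_id[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).upper(),
            alt_loc="",
            res_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
            res_seq=int(arr.res_id[i]),
            position=np.array(arr.coord[i], dtype=float),
            occupancy=float(arr.occupancy[i]),
            i_code=str(ins[i]).strip(),
            hetero=bool(arr.hetero[i]),
        ))
    if not atoms:
        raise StructureParseError(f"{path}: no atom_site records found")
    return atoms


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-column PDB ATOM/HETATM records."""
    path = Path(path)
    with open(path, "w") as handle:
        if model.label:
            handle.write(f"TITLE     {model.label[:60]}\n")
        serial = 0
        for atom in model.atoms:
            serial = (serial % 99999) + 1
            record = "HETATM" if atom.hetero else "ATOM  "
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.position
            handle.write(
                f"{record}{serial:5d} {name:<4.4s}{atom.alt_loc or ' ':1.1s}"
                f"{atom.res_name:>3.3s} {atom.chain_id[:1] or 'A':1s}"
                f"{atom.res_seq:4d}{atom.i_code or ' ':1.1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2.2s}\n"
            )
        handle.write("END\n")


def export_atom_table(model: StructureModel, path: str | Path) -> None:
    """Dump the atom list as a TSV table (one row per atom)."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["serial", "name", "element", "res_name", "chain_id",
                         "res_seq", "i_code", "x", "y", "z", "occupancy",
                         "vdw_radius", "hetero"])
        for a in model.atoms:
            writer.writerow([a.serial, a.name, a.element, a.res_name,
                             a.chain_id, a.res_seq, a.i_code,
                             f"{a.position[0]:.3f}", f"{a.position[1]:.3f}",
                             f"{a.position[2]:.3f}", f"{a.occupancy:.2f}",
                             "" if a.vdw_radius is None else f"{a.vdw_radius:.2f}",
                             int(a.hetero)])


# ---------------------------------------------------------------------------
# Radii and transforms
# ---------------------------------------------------------------------------

def assign_radii(model: StructureModel,
                 radius_set: Mapping[str, float] = BONDI_RADII,
                 default: float = DEFAULT_RADIUS) -> StructureModel:
    """Assign van der Waals radii by element; unknown elements get `default`.

    Idempotent and total: every atom ends up with a positive radius.
    """
    model = model.copy()
    unknown: set[str] = set()
    for atom in model.atoms:
        radius = radius_set.get(atom.element.upper())
        if radius is None:
            unknown.add(atom.element)
            radius = default
        atom.vdw_radius = radius
    if unknown:
        warnings.warn(
            f"elements {sorted(unknown)} missing from radius table; "
            f"using default {default} Å", stacklevel=2)
    return model


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Apply a rigid transform to every atom position; topology unchanged."""
    if not isinstance(t, RigidTransform):
        raise TypeError("t must be a RigidTransform")
    return model.with_coords(t.apply(model.coords))
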