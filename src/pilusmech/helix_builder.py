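"""Helical symmetry: descriptors derived from (twist, rise) and construction
of an n-subunit filament from one asymmetric unit about the z-axis.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from pilusmech.structure_core import RigidTransform, StructureModel, apply_transform

__all__ = [
    "HelicalParams",
    "HelicalDescriptors",
    "FilamentModel",
    "derived_descriptors",
    "symmetry_operator",
    "build_filament",
    "radial_profile",
]

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class HelicalParams:
    """Azimuthal twist (deg) and axial rise (Å) per subunit of a 1-start helix."""

    twist_deg: float
    rise_ang: float
    handedness: str = "right"

    def __post_init__(self) -> None:
        if not 0 < self.twist_deg < 360:
            raise ValueError("twist_deg must be in (0, 360)")
        if self.rise_ang <= 0:
            raise ValueError("rise_ang must be positive")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")


@dataclass(frozen=True)
class HelicalDescriptors:
    subunits_per_turn: float
    pitch_ang: float
    subunits_per_micron: float
    start_number: int = 1


@dataclass
class FilamentModel:
    """Symmetry copies of one asymmetric unit, keyed by signed subunit index."""

    subunits: dict[int, StructureModel] = field(default_factory=dict)
    params: HelicalParams | None = None

    def __len__(self) -> int:
        return len(self.subunits)

    def indices(self) -> list[int]:
        return sorted(self.subunits)

    def merged(self) -> StructureModel:
        """Single model with all subunits concatenated in index order."""
        atoms = []
        for k in self.indices():
            atoms.extend(a.copy() for a in self.subunits[k].atoms)
        return StructureModel(atoms=atoms, label="filament")


def derived_descriptors(params: HelicalParams) -> HelicalDescriptors:
    """Subunits per turn, pitch, and subunits per micron from (twist, rise).

    No rounding is applied; presentation layers round for display.
    """
    spt = 360.0 / params.twist_deg
    return HelicalDescriptors(
        subunits_per_turn=spt,
        pitch_ang=spt * params.rise_ang,
        subunits_per_micron=10000.0 / params.rise_ang,
    )


def symmetry_operator(params: HelicalParams, k: int) -> RigidTransform:
    """Rigid transform taking subunit 0 onto subunit k.

    Rotation about z by k*twist composed with translation (0, 0, k*rise).
    Right-handed helices advance +z with positive (counter-clockwise)
    rotation; left-handed helices use the opposite rotation sign.
    """
    sign = 1.0 if params.handedness == "right" else -1.0
    theta = sign * np.deg2rad(k * params.twist_deg)
    c, s = np.cos(theta), np.sin(theta)
    rotation = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    translation = np.array([0.0, 0.0, k * params.rise_ang])
    return RigidTransform(rotation, translation)


def build_filament(asym: StructureModel, params: HelicalParams,
                   k_min: int, k_max: int) -> FilamentModel:
    """Replicate the asymmetric unit over subunit indices k_min..k_max.

    The asymmetric unit must already be posed in the filament frame with the
    helix axis along z. Subunit 0 is the untransformed input; chain ids of
    copies are rotated through a 62-character alphabet for PDB output.
    """
    if not (k_min <= 0 <= k_max):
        raise ValueError("require k_min <= 0 <= k_max")
    base_chains = asym.chain_ids()
    n_copies = k_max - k_min + 1
    if n_copies * len(base_chains) > len(_CHAIN_ALPHABET):
        raise ValueError(
            f"{n_copies} copies x {len(base_chains)} chains exceeds the "
            f"{len(_CHAIN_ALPHABET)}-character chain-id alphabet; reduce the "
            "range or merge chains before building")
    subunits: dict[int, StructureModel] = {}
    chain_counter = 0
    chain_map_cache: dict[int, dict[str, str]] = {}
    for k in range(k_min, k_max + 1):
        copy = apply_transform(asym, symmetry_operator(params, k))
        chain_map: dict[str, str] = {}
        for cid in base_chains:
            chain_map[cid] = _CHAIN_ALPHABET[chain_counter]
            chain_counter += 1
        for atom in copy.atoms:
            atom.chain_id = chain_map[atom.chain_id]
        copy.label = f"{asym.label}:k={k:+d}"
        subunits[k] = copy
        chain_map_cache[k] = chain_map
    return FilamentModel(subunits=subunits, params=params)


def radial_profile(model: FilamentModel | StructureModel) -> dict[str, float]:
    """Radial extent and a fourth-moment stiffness proxy about the z-axis.

    Returns max_radius (atom-center radius plus its vdW radius), diameter,
    and r4_moment = sum over atoms of (x^2+y^2)^2 divided by the subunit
    count — a comparative bending-stiffness proxy, not an absolute rigidity.
    """
    if isinstance(model, FilamentModel):
        n_subunits = len(model.subunits)
        merged = model.merged()
    else:
        n_subunits = 1
        merged = model
    if len(merged) == 0:
        raise ValueError("empty model")
    coords = merged.coords
    radii = merged.radii
    r2 = coords[:, 0] ** 2 + coords[:, 1] ** 2
    max_radius = float(np.max(np.sqrt(r2) + radii))
    return {
        "max_radius": max_radius,
        "diameter": 2.0 * max_radius,
        "r4_moment": float(np.sum(r2 ** 2) / n_subunits),
    }
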