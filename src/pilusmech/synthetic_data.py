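"""Seeded synthetic-data generators for every input class the analysis
modules consume: a toy helical subunit with tunable packing, 2D-equilibrium
worm-like-chain traces, AFM force-distance curves with nanospring / plateau
signatures, and prepilin FASTA sets with planted motifs and taxonomy.

Determinism: one root seed fans out to per-item sub-seeds through
``np.random.default_rng([seed, index, ...])`` so changing the item count
never reshuffles earlier items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pilusmech.afm_fd import FDCurve
from pilusmech.filament_mechanics import Trace2D
from pilusmech.pilin_survey import PrepilinRecord
from pilusmech.structure_core import AtomRecord, StructureModel

__all__ = [
    "GeneratorSpec",
    "make_toy_subunit",
    "simulate_wlc_traces",
    "simulate_fd_curves",
    "simulate_prepilin_set",
]


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int
    kind: str       # toy_subunit | wlc_traces | fd_curves | prepilin_set
    params: dict = field(default_factory=dict)

    _KINDS = ("toy_subunit", "wlc_traces", "fd_curves", "prepilin_set")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")

    def get(self, key, default):
        return self.params.get(key, default)


# ---------------------------------------------------------------------------
# Toy subunit
# ---------------------------------------------------------------------------

def _fibonacci_ball(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points filling a ball of given radius."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    shell = radius * ((i + 0.5) / n) ** (1.0 / 3.0)
    return np.column_stack([shell * rho * np.cos(phi),
                            shell * rho * np.sin(phi),
                            shell * z])


def make_toy_subunit(spec: GeneratorSpec) -> StructureModel:
    """Pseudo-pilin: an ideal tilted alpha-helix plus a globular atom cluster.

    The helix (1.5 Å rise and 100 degrees per residue, CA plus a dummy
    side-chain sphere per residue) starts near the filament axis and tilts
    outward with +z; the globule sits at `radial_offset` from the axis near
    the helix top. Defaults are chosen so that copies related by
    (twist 100.7 degrees, rise 10 Å) touch at several neighbor offsets.
    """
    helix_len = int(spec.get("helix_len", 52))
    globule_radius = float(spec.get("globule_radius", 11.0))
    radial_offset = float(spec.get("radial_offset", 13.0))
    sphere_radius = float(spec.get("sphere_radius", 3.0))
    n_globule = int(spec.get("n_globule", 80))

    if globule_radius < 0 or radial_offset < 0:
        raise ValueError("globule_radius and radial_offset must be >= 0")
    if globule_radius > 0 and radial_offset < 0.5 * globule_radius:
        raise ValueError(
            "globule overlaps the filament axis (self-intersection): "
            "require radial_offset >= globule_radius / 2")

    atoms: list[AtomRecord] = []
    serial = 1
    # local-helix axis tilting from (2.5, 0, 0) outward to larger radius
    z_top = 1.5 * (helix_len - 1)
    axis_start = np.array([2.5, 0.0, 0.0])
    axis_end = np.array([9.0, 0.0, z_top])
    for i in range(helix_len):
        t = i / max(helix_len - 1, 1)
        center = axis_start + t * (axis_end - axis_start)
        angle = np.deg2rad(100.0 * i)
        ca = center + 2.3 * np.array([np.cos(angle), np.sin(angle), 0.0])
        atoms.append(AtomRecord(serial=serial, name="CA", element="C",
                                alt_loc="", res_name="ALA", chain_id="A",
                                res_seq=i + 1, position=ca,
                                vdw_radius=sphere_radius))
        serial += 1
    if globule_radius > 0:
        center = np.array([radial_offset, 0.0, z_top - 12.0])
        for j, offset in enumerate(_fibonacci_ball(n_globule, globule_radius)):
            atoms.append(AtomRecord(serial=serial, name="CB", element="C",
                                    alt_loc="", res_name="GLB", chain_id="A",
                                    res_seq=helix_len + 1 + j,
                                    position=center + offset,
                                    vdw_radius=sphere_radius))
            serial += 1
        # self-intersection guard: globule must not swallow the helix
        helix_xyz = np.stack([a.position for a in atoms[:helix_len]])
        dmin = np.min(np.linalg.norm(helix_xyz - center, axis=1))
        if dmin < 0.25 * globule_radius:
            raise ValueError("globule engulfs the helix (self-intersection)")
    return StructureModel(atoms=atoms, label="toy_subunit",
                          provenance=f"synthetic:seed={spec.seed}")


# ---------------------------------------------------------------------------
# Worm-like-chain traces
# ---------------------------------------------------------------------------

def simulate_wlc_traces(spec: GeneratorSpec) -> list[Trace2D]:
    """2D-equilibrium worm-like-chain contours.

    Tangent angle performs a Gaussian walk with per-step variance ds/Lp (the
    2D convention, giving <cos theta(s)> = exp(-s/2Lp)); positions follow by
    cumulative sum of unit tangents scaled by ds. Each trace draws from an
    independent sub-seed.
    """
    lp_um = float(spec.get("lp_um", 21.0))
    contour_um = float(spec.get("contour_um", 4.0))
    ds_nm = float(spec.get("ds_nm", 10.0))
    n_traces = int(spec.get("n_traces", 200))
    lp_nm = lp_um * 1000.0
    if ds_nm >= lp_nm:
        raise ValueError("ds must be smaller than the persistence length")
    n_steps = int(round(contour_um * 1000.0 / ds_nm))
    sigma = np.sqrt(ds_nm / lp_nm)
    traces = []
    for i in range(n_traces):
        rng = np.random.default_rng([spec.seed, 1, i])
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        theta = theta0 + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, sigma, n_steps - 1))])
        steps = ds_nm * np.column_stack([np.cos(theta), np.sin(theta)])
        points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        traces.append(Trace2D(points=points, pixel_size=ds_nm,
                              label=f"wlc_{lp_um:g}um_{i}"))
    return traces


# ---------------------------------------------------------------------------
# Force-distance curves
# ---------------------------------------------------------------------------

def _make_spring(d: np.ndarray, rng, k: float, f_adh: float,
                 d0: float) -> np.ndarray:
    f = np.zeros_like(d)
    d_rupture = d0 + f_adh / k
    loading = (d >= d0) & (d <= d_rupture)
    f[loading] = k * (d[loading] - d0)
    return f, d_rupture


def _make_plateau(d: np.ndarray, rng, force: float, d0: float,
                  length: float, rise_slope: float = 20.0) -> np.ndarray:
    f = np.zeros_like(d)
    d_top = d0 + force / rise_slope
    d_rupture = d_top + length
    rising = (d >= d0) & (d < d_top)
    flat = (d >= d_top) & (d <= d_rupture)
    f[rising] = rise_slope * (d[rising] - d0)
    f[flat] = force
    return f, d_rupture


def simulate_fd_curves(spec: GeneratorSpec) -> list[FDCurve]:
    """Labeled retraction force-distance curves.

    params: n_curves, mix (dict of kind -> fraction over nanospring /
    plateau / both / none), k_mean/k_sd (pN/nm), f_adh_mean/f_adh_sd (pN),
    plateau_force_mean/sd (pN), plateau_len range (nm), noise_sd (pN),
    baseline_offset (pN), drift (pN/nm), d_max and ds (nm). Ground truth is
    attached under curve.meta. Rupture is an instantaneous return to
    baseline.
    """
    n_curves = int(spec.get("n_curves", 100))
    mix = dict(spec.get("mix", {"nanospring": 0.4, "plateau": 0.3,
                                "none": 0.3}))
    k_mean = float(spec.get("k_mean", 5.5))
    k_sd = float(spec.get("k_sd", 1.0))
    f_adh_mean = float(spec.get("f_adh_mean", 120.0))
    f_adh_sd = float(spec.get("f_adh_sd", 20.0))
    plateau_force_mean = float(spec.get("plateau_force_mean", 220.0))
    plateau_force_sd = float(spec.get("plateau_force_sd", 30.0))
    plateau_len_range = tuple(spec.get("plateau_len_range", (80.0, 200.0)))
    noise_sd = float(spec.get("noise_sd", 5.0))
    baseline_offset = float(spec.get("baseline_offset", 0.0))
    drift = float(spec.get("drift", 0.0))
    d_max = float(spec.get("d_max", 500.0))
    ds = float(spec.get("ds", 0.5))
    retract_speed = float(spec.get("retract_speed", 1.0))
    for name, value in (("k_mean", k_mean), ("f_adh_mean", f_adh_mean),
                        ("plateau_force_mean", plateau_force_mean),
                        ("noise_sd", noise_sd), ("d_max", d_max), ("ds", ds)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")

    kinds = sorted(mix)
    fractions = np.array([mix[k] for k in kinds], dtype=float)
    fractions = fractions / fractions.sum()
    d = np.arange(0.0, d_max + ds / 2, ds)
    curves = []
    for i in range(n_curves):
        rng = np.random.default_rng([spec.seed, 2, i])
        kind = kinds[int(rng.choice(len(kinds), p=fractions))]
        truth: dict = {"kind": kind}
        f = np.zeros_like(d)
        if kind == "nanospring":
            k = max(rng.normal(k_mean, k_sd), 0.5)
            f_adh = max(rng.normal(f_adh_mean, f_adh_sd), 60.0)
            d0 = rng.uniform(10.0, 60.0)
            f, d_rupture = _make_spring(d, rng, k, f_adh, d0)
            truth.update(k_pilus=k, f_adh=f_adh, rupture_distance=d_rupture)
        elif kind == "plateau":
            force = max(rng.normal(plateau_force_mean, plateau_force_sd), 60.0)
            d0 = rng.uniform(10.0, 60.0)
            length = rng.uniform(*plateau_len_range)
            f, d_rupture = _make_plateau(d, rng, force, d0, length)
            truth.update(plateau_force=force, plateau_len=length,
                         rupture_distance=d_rupture)
        elif kind == "both":
            k = max(rng.normal(k_mean, k_sd), 0.5)
            force = max(rng.normal(plateau_force_mean, plateau_force_sd), 60.0)
            d0 = rng.uniform(10.0, 40.0)
            length = rng.uniform(*plateau_len_range)
            d_top = d0 + force / k
            d_rupture = d_top + length
            rising = (d >= d0) & (d < d_top)
            flat = (d >= d_top) & (d <= d_rupture)
            f[rising] = k * (d[rising] - d0)
            f[flat] = force
            truth.update(k_pilus=k, plateau_force=force, plateau_len=length,
                         rupture_distance=d_rupture)
        elif kind != "none":
            raise ValueError(f"unknown curve kind {kind!r}")
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, len(d))
        f = f + baseline_offset + drift * d
        curves.append(FDCurve(distance=d.copy(), force=f,
                              retract_speed=retract_speed,
                              label=f"fd_{kind}_{i}", meta={"truth": truth}))
    return curves


# ---------------------------------------------------------------------------
# Prepilin sets
# ---------------------------------------------------------------------------

_RESIDUES = np.array(list("ACDEFHIKLMNPQRSTVWY"))      # no G: keeps the
_RESIDUES_ALL = np.array(list("ACDEFGHIKLMNPQRSTVWY"))  # planted motif first


def _one_prepilin(rng, mature_len: int, p22: float) -> str:
    sp_len = int(rng.integers(5, 31))
    sp = "".join(rng.choice(_RESIDUES, sp_len))       # G-free signal peptide
    core = "".join(rng.choice(_RESIDUES, 3))
    tail_len = mature_len - 5
    tail = list(rng.choice(_RESIDUES_ALL, tail_len))
    # avoid a second motif inside the 60-residue scan window
    for j in range(len(tail) - 1):
        if tail[j] == "G" and tail[j + 1] in "FILMV":
            tail[j + 1] = "A"
    if rng.random() < p22 and mature_len >= 22:
        tail[22 - 5 - 1] = "P"      # mature position 22 (F = position 1)
    return sp + "G" + "F" + core + "E" + "".join(tail)


def simulate_prepilin_set(spec: GeneratorSpec,
                          ) -> tuple[list[PrepilinRecord], dict]:
    """Prepilin records with planted cleavage motifs and taxonomy labels.

    params: taxa — list of dicts with keys name, phylum, class (optional,
    defaults to name), n, length_mean, length_sd, frac_large (optional);
    p22 (planted Pro22 frequency, default 0.8); dup_rate (fraction of extra
    ~95%-identity duplicates, default 0). Mature lengths are drawn from the
    per-taxon normal, clipped to [42, 297] (large draws clipped to the
    threshold boundary when frac_large is given). Returns (records, truth).
    """
    taxa = spec.get("taxa", [{"name": "SimPhylum", "phylum": "SimPhylum",
                              "class": "SimClass", "n": 100,
                              "length_mean": 141, "length_sd": 25}])
    p22 = float(spec.get("p22", 0.8))
    dup_rate = float(spec.get("dup_rate", 0.0))
    large_threshold = int(spec.get("large_threshold", 166))

    records: list[PrepilinRecord] = []
    truth: dict = {"cleavage": {}, "taxon_counts": {}, "duplicates": {}}
    for t_idx, taxon in enumerate(taxa):
        name = taxon["name"]
        phylum = taxon.get("phylum", name)
        klass = taxon.get("class", name)
        n = int(taxon["n"])
        mean = float(taxon.get("length_mean", 141))
        sd = float(taxon.get("length_sd", 25))
        frac_large = taxon.get("frac_large")
        if mean < 42 or mean > 297:
            raise ValueError(f"taxon {name}: infeasible length target {mean}")
        n_large_planted = 0
        for i in range(n):
            rng = np.random.default_rng([spec.seed, 3, t_idx, i])
            if frac_large is not None:
                if rng.random() < frac_large:
                    mature_len = int(np.clip(round(rng.normal(190, 15)),
                                             large_threshold, 297))
                else:
                    mature_len = int(np.clip(round(rng.normal(141, 20)),
                                             42, large_threshold - 1))
            else:
                mature_len = int(np.clip(round(rng.normal(mean, sd)), 42, 297))
            if mature_len >= large_threshold:
                n_large_planted += 1
            seq = _one_prepilin(rng, mature_len, p22)
            rec_id = f"{name}_{i:04d}"
            records.append(PrepilinRecord(id=rec_id, sequence=seq,
                                          phylum=phylum, klass=klass))
            truth["cleavage"][rec_id] = len(seq) - mature_len - 1
        truth["taxon_counts"][name] = {"n": n, "n_large": n_large_planted}

    if dup_rate > 0:
        n_dups = int(round(dup_rate * len(records)))
        base = list(records)
        for j in range(n_dups):
            rng = np.random.default_rng([spec.seed, 4, j])
            parent = base[int(rng.integers(0, len(base)))]
            seq = list(parent.sequence)
            cleavage = truth["cleavage"][parent.id]
            n_mut = max(int(round(0.05 * len(seq))), 1)
            # mutate only past the scan window to keep the motif intact
            lo = cleavage + 6
            if lo >= len(seq) - n_mut:
                continue
            sites = rng.choice(np.arange(lo, len(seq)), n_mut, replace=False)
            for site in sites:
                seq[site] = str(rng.choice(_RESIDUES))
            dup_id = f"{parent.id}_dup{j}"
            records.append(PrepilinRecord(id=dup_id, sequence="".join(seq),
                                          phylum=parent.phylum,
                                          klass=parent.klass))
            truth["cleavage"][dup_id] = cleavage
            truth["duplicates"][dup_id] = parent.id
    return records, truth
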