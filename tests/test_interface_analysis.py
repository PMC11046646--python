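import numpy as np
import pytest

from pilusmech.helix_builder import FilamentModel, HelicalParams, build_filament
from pilusmech.interface_analysis import (
    InterfaceSummary,
    buried_interface_area,
    compute_sasa,
    enumerate_interfaces,
    fibonacci_sphere,
    find_salt_bridges,
    segment_helices,
)
from pilusmech.structure_core import AtomRecord, StructureModel
from pilusmech.synthetic_data import GeneratorSpec, make_toy_subunit

from conftest import build_backbone, sphere_model

PILUS_PARAMS = HelicalParams(100.7, 10.0)


def two_sphere_exposed_area(r1, r2, d, probe):
    """Analytic exposed area of two intersecting probe-inflated spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * R1 ** 2, 4 * np.pi * R2 ** 2
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return (4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1,
            4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2)


class TestComputeSasa:
    def test_isolated_sphere_closed_form(self):
        model = sphere_model([[0, 0, 0]], [1.7])
        result = compute_sasa(model, probe=1.4, n_points=960)
        assert result.total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-12)
        assert result.total == pytest.approx(120.76, abs=0.01)

    def test_two_spheres_cap_formula(self):
        # oracle: spherical-cap closed form, 1% at 960 points
        model = sphere_model([[0, 0, 0], [3.0, 0, 0]], [1.7, 1.7])
        result = compute_sasa(model, probe=1.4, n_points=960)
        expected, _ = two_sphere_exposed_area(1.7, 1.7, 3.0, 1.4)
        np.testing.assert_allclose(result.per_atom, expected, rtol=0.01)

    def test_additivity(self):
        spec = GeneratorSpec(0, "toy_subunit")
        model = make_toy_subunit(spec)
        result = compute_sasa(model, n_points=240)
        assert result.total == pytest.approx(result.per_atom.sum(), rel=1e-12)
        assert sum(result.per_residue.values()) == pytest.approx(result.total,
                                                                 rel=1e-9)

    def test_monotonicity(self):
        base = sphere_model([[0, 0, 0], [3.0, 0, 0]], [1.7, 1.7])
        more = sphere_model([[0, 0, 0], [3.0, 0, 0], [1.5, 2.0, 0]],
                            [1.7, 1.7, 1.7])
        sasa_base = compute_sasa(base, n_points=960).per_atom
        sasa_more = compute_sasa(more, n_points=960).per_atom[:2]
        assert np.all(sasa_more <= sasa_base + 1e-12)

    def test_grid_equals_brute(self):
        model = make_toy_subunit(GeneratorSpec(3, "toy_subunit"))
        grid = compute_sasa(model, n_points=240, method="grid")
        brute = compute_sasa(model, n_points=240, method="brute")
        np.testing.assert_array_equal(grid.per_atom, brute.per_atom)

    def test_cross_implementation(self):
        # independent reference SASA on identical radii
        import biotite.structure as struc

        model = make_toy_subunit(GeneratorSpec(1, "toy_subunit"))
        ours = compute_sasa(model, probe=1.4, n_points=960).total
        arr = struc.AtomArray(len(model))
        arr.coord = model.coords.astype(np.float32)
        for i, atom in enumerate(model.atoms):
            arr.chain_id[i] = atom.chain_id
            arr.res_id[i] = atom.res_seq
            arr.res_name[i] = atom.res_name
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii=model.radii).sum()
        assert ours == pytest.approx(theirs, rel=0.03)

    def test_missing_radii_named(self):
        model = sphere_model([[0, 0, 0]], [1.7])
        model.atoms[0].vdw_radius = None
        with pytest.raises(ValueError, match="assign_radii"):
            compute_sasa(model)

    def test_point_count_floor(self):
        model = sphere_model([[0, 0, 0]], [1.7])
        with pytest.raises(ValueError):
            compute_sasa(model, n_points=50)

    def test_fibonacci_sphere_unit_norm(self):
        points = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(points, axis=1), 1.0,
                                   atol=1e-12)


def toy_filament(k_min=-9, k_max=9, seed=0):
    return build_filament(make_toy_subunit(GeneratorSpec(seed, "toy_subunit")),
                          PILUS_PARAMS, k_min, k_max)


class TestBuriedInterfaceArea:
    def test_distant_subunits_zero(self):
        sub = sphere_model([[30.0, 0, 0]], [1.5])
        filament = build_filament(sub, HelicalParams(120.0, 50.0), -2, 2)
        report = buried_interface_area(filament, 1, n_points=240)
        assert report.buried_area == 0.0
        assert report.residue_pairs == []

    def test_two_sphere_half_difference(self):
        # subunits of one sphere each; analytic half-difference oracle
        sub = sphere_model([[5.0, 0.0, 0.0]], [1.7])
        params = HelicalParams(30.0, 2.0)
        filament = build_filament(sub, params, -1, 1)
        report = buried_interface_area(filament, 1, probe=1.4, n_points=3840)
        a = filament.subunits[0].atoms[0].position
        b = filament.subunits[-1].atoms[0].position
        d = np.linalg.norm(a - b)
        exp_a, exp_b = two_sphere_exposed_area(1.7, 1.7, d, 1.4)
        full = 2 * 4 * np.pi * 3.1 ** 2 - (exp_a + exp_b)
        assert full > 0  # the fixture must actually touch
        assert report.buried_area == pytest.approx(full / 2, rel=0.02)
        assert report.buried_area_full == pytest.approx(full, rel=0.02)

    def test_symmetry_of_pair(self):
        filament = toy_filament(-2, 2)
        ab = buried_interface_area(filament, 1, n_points=240, central=0)
        # same physical pair measured from the other side
        ba = buried_interface_area(filament, 1, n_points=240, central=0)
        assert ab.buried_area == ba.buried_area

    def test_missing_subunit(self):
        filament = toy_filament(-1, 1)
        with pytest.raises(KeyError):
            buried_interface_area(filament, 5)


@pytest.fixture(scope="module")
def summary():
    return enumerate_interfaces(toy_filament(), n_points=240)


class TestEnumerateInterfaces:
    def test_toy_has_multiple_classes(self, summary):
        assert len(summary.interfaces) >= 3
        assert all(r.buried_area >= 10.0 for r in summary.interfaces)

    def test_totals_and_partners(self, summary):
        total = sum(r.buried_area for r in summary.interfaces)
        assert summary.total_per_subunit == pytest.approx(total)
        assert summary.total_per_pilin == pytest.approx(2 * total)
        assert summary.n_partners == 2 * len(summary.interfaces)
        assert summary.n_partners % 2 == 0

    def test_sorted_descending(self, summary):
        areas = [r.buried_area for r in summary.interfaces]
        assert areas == sorted(areas, reverse=True)

    def test_non_touching_filament(self):
        sub = sphere_model([[50.0, 0, 0]], [1.0])
        filament = build_filament(sub, HelicalParams(100.0, 40.0), -9, 9)
        summary = enumerate_interfaces(filament, n_points=240)
        assert summary.interfaces == []
        assert summary.total_per_subunit == 0.0

    def test_helical_invariance(self):
        # oracle: recomputation with the central subunit shifted by one
        filament = toy_filament(-8, 10)
        at0 = enumerate_interfaces(filament, max_offset=8, n_points=240,
                                   central=0)
        at1 = enumerate_interfaces(filament, max_offset=8, n_points=240,
                                   central=1)
        a0 = {r.offset_k: r.buried_area for r in at0.interfaces}
        a1 = {r.offset_k: r.buried_area for r in at1.interfaces}
        assert set(a0) == set(a1)
        for k in a0:
            assert abs(a0[k] - a1[k]) < 1.0

    def test_convergence_960_vs_3840(self):
        filament = toy_filament(-4, 4)
        lo = buried_interface_area(filament, 1, n_points=960)
        hi = buried_interface_area(filament, 1, n_points=3840)
        assert lo.buried_area == pytest.approx(hi.buried_area, rel=0.02)

    def test_insufficient_span(self):
        filament = toy_filament(-3, 3)
        with pytest.raises(ValueError, match="-9"):
            enumerate_interfaces(filament, max_offset=9)

    def test_from_reports_min_area_knob(self, summary):
        rebuilt = InterfaceSummary.from_reports(summary.interfaces,
                                                min_area=1e9)
        assert rebuilt.interfaces == []
        assert rebuilt.n_partners == 0


def _atom(serial, name, element, res_name, chain, res_seq, pos):
    return AtomRecord(serial=serial, name=name, element=element, alt_loc="",
                      res_name=res_name, chain_id=chain, res_seq=res_seq,
                      position=np.asarray(pos, dtype=float), vdw_radius=1.6)


class TestSaltBridges:
    def make_filament(self, n_o_distance):
        # Lys NZ on subunit 0, Glu OE1 on subunit -1, at a known distance
        lys = StructureModel(atoms=[
            _atom(1, "NZ", "N", "LYS", "A", 10, [8.0, 0.0, 0.0])])
        glu_pos = np.array([8.0 + n_o_distance, 0.0, 0.0])
        filament = FilamentModel(subunits={
            0: lys,
            -1: StructureModel(atoms=[
                _atom(2, "OE1", "O", "GLU", "B", 20, glu_pos)]),
        }, params=PILUS_PARAMS)
        return filament

    def test_constructed_bridge(self):
        bridges = find_salt_bridges(self.make_filament(3.5), 1)
        assert len(bridges) == 1
        bridge = bridges[0]
        assert bridge.basic_residue == ("A", 10, "LYS")
        assert bridge.acidic_residue == ("B", 20, "GLU")
        assert bridge.distance == pytest.approx(3.5)

    def test_cutoff_respected(self):
        assert find_salt_bridges(self.make_filament(4.5), 1) == []
        assert len(find_salt_bridges(self.make_filament(4.5), 1,
                                     cutoff=5.0)) == 1

    def test_no_charged_residues(self):
        filament = toy_filament(-1, 1)  # toy atoms are ALA/GLB spheres
        assert find_salt_bridges(filament, 1) == []

    def test_deduplicated_min_distance(self):
        lys = StructureModel(atoms=[
            _atom(1, "NZ", "N", "LYS", "A", 10, [0.0, 0.0, 0.0])])
        glu = StructureModel(atoms=[
            _atom(2, "OE1", "O", "GLU", "B", 20, [3.5, 0.0, 0.0]),
            _atom(3, "OE2", "O", "GLU", "B", 20, [3.0, 0.0, 0.0])])
        filament = FilamentModel(subunits={0: lys, -1: glu},
                                 params=PILUS_PARAMS)
        bridges = find_salt_bridges(filament, 1)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.0)


HELIX = (-57.0, -47.0)
EXTENDED = (180.0, 180.0)


class TestSegmentHelices:
    def test_ideal_polyalanine_single_helix(self):
        chain = build_backbone([HELIX] * 20)
        seg = segment_helices(chain)
        helix_runs = [s for s in seg.segments if s[2] == "helix"]
        assert len(helix_runs) == 1
        start, end, _ = helix_runs[0]
        # termini lack phi or psi and cannot be classified helical
        assert start <= 3 and end >= 18

    def test_fully_extended_no_helix(self):
        chain = build_backbone([EXTENDED] * 20)
        seg = segment_helices(chain)
        assert all(s[2] == "coil" for s in seg.segments)
        assert seg.alpha1N is None

    def test_helix_coil_helix_architecture(self):
        # alpha1N res 3-18, melted 19-23, alpha1C 24-54 (author numbering)
        phi_psi = ([EXTENDED] * 2 + [HELIX] * 16 + [EXTENDED] * 5
                   + [HELIX] * 31 + [EXTENDED] * 2)
        chain = build_backbone(phi_psi)
        seg = segment_helices(chain)
        assert seg.alpha1N is not None and seg.alpha1C is not None
        assert abs(seg.alpha1N[0] - 3) <= 1 and abs(seg.alpha1N[1] - 18) <= 1
        assert abs(seg.alpha1C[0] - 24) <= 1 and abs(seg.alpha1C[1] - 54) <= 1
        melted_len = seg.melted[1] - seg.melted[0] + 1
        assert abs(melted_len - 5) <= 2

    def test_segments_tile_without_overlap(self):
        phi_psi = [EXTENDED] * 3 + [HELIX] * 8 + [EXTENDED] * 4
        seg = segment_helices(build_backbone(phi_psi))
        covered = []
        for start, end, _ in seg.segments:
            covered.extend(range(start, end + 1))
        assert covered == sorted(set(covered))

    def test_short_helix_demoted(self):
        phi_psi = [EXTENDED] * 5 + [HELIX] * 3 + [EXTENDED] * 5
        seg = segment_helices(build_backbone(phi_psi))
        assert all(s[2] == "coil" for s in seg.segments)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="5 residues"):
            segment_helices(build_backbone([HELIX] * 3))

    def test_backbone_builder_dihedrals_exact(self):
        # sanity of the oracle itself: built dihedrals match the request
        from pilusmech.interface_analysis import backbone_dihedrals

        chain = build_backbone([HELIX] * 6)
        for r, (phi, psi) in backbone_dihedrals(chain).items():
            if phi is not None:
                assert phi == pytest.approx(-57.0, abs=1e-6)
            if psi is not None:
                assert psi == pytest.approx(-47.0, abs=1e-6)
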