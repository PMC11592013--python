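"""Mesh container, tie constraints and the synthetic geometry generators."""

import warnings

import numpy as np
import pytest

from osteoimpact import Mesh, PlateSpec, ArchSpec, make_impactor, make_layered_plate, make_single_element, make_zygoma_arch, merge_tie
from osteoimpact.mesh import MeshError, PHASE_CORTICAL, PHASE_TRABECULAR
from osteoimpact import units


@pytest.fixture(scope="module")
def plate_mesh():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_layered_plate(PlateSpec())


class TestSingleElement:
    def test_volume_and_mass(self, cortical):
        m = make_single_element(1.0)
        assert m.element_volumes()[0] == pytest.approx(1.0)
        mass_g = cortical.elastic.density * m.element_volumes().sum() * 1e6  # tonne -> g
        assert mass_g == pytest.approx(2.12e-3)  # 2.12 mg for a 1 mm^3 cube

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            make_single_element(0.0)

    def test_face_sets_complete(self):
        m = make_single_element(2.0)
        for name in ("x0", "x1", "y0", "y1", "z0", "z1"):
            assert len(m.node_sets[name]) == 4


class TestLayeredPlate:
    def test_phase_volume_fractions(self, plate_mesh):
        spec = PlateSpec()
        vols = plate_mesh.element_volumes()
        cort = vols[plate_mesh.phase == PHASE_CORTICAL].sum()
        trab = vols[plate_mesh.phase == PHASE_TRABECULAR].sum()
        expect_cort = 2 * spec.cortical_thickness / spec.thickness
        got = cort / (cort + trab)
        assert got == pytest.approx(expect_cort, rel=0.05)

    def test_flat_plate_layers_coplanar(self, plate_mesh):
        z = plate_mesh.nodes[:, 2]
        levels = np.unique(np.round(z, 9))
        for lv in levels:
            sel = np.isclose(z, lv)
            assert np.ptp(plate_mesh.nodes[sel, 2]) < 1e-12

    def test_total_volume_matches_block(self, plate_mesh):
        spec = PlateSpec()
        assert plate_mesh.element_volumes().sum() == pytest.approx(spec.span * spec.width * spec.thickness, rel=1e-9)

    def test_node_sets_present_and_disjoint_faces(self, plate_mesh):
        assert len(plate_mesh.node_sets["fixed"]) > 0
        assert len(plate_mesh.node_sets["impact_face"]) > 0
        assert len(plate_mesh.node_sets["back_face"]) > 0
        assert not set(plate_mesh.node_sets["impact_face"]) & set(plate_mesh.node_sets["back_face"])

    def test_cortical_thickness_bounds_enforced(self):
        with pytest.raises(ValueError):
            PlateSpec(cortical_thickness=1.0)

    def test_curved_plate_preserves_validity(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = make_layered_plate(PlateSpec(curvature_radius=60.0))
        m.validate()
        # curvature actually bends the sheet out of plane
        assert np.ptp(m.nodes[:, 2]) > PlateSpec().thickness

    def test_jitter_deterministic_given_seed(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = make_layered_plate(PlateSpec(jitter=0.1, seed=42))
            b = make_layered_plate(PlateSpec(jitter=0.1, seed=42))
            c = make_layered_plate(PlateSpec(jitter=0.1, seed=43))
        np.testing.assert_array_equal(a.nodes, b.nodes)
        assert not np.array_equal(a.nodes, c.nodes)


class TestArch:
    def test_two_disjoint_fixed_abutments(self):
        m = make_zygoma_arch(ArchSpec())
        a, b = m.node_sets["abutment_a"], m.node_sets["abutment_b"]
        assert len(a) > 0 and len(b) > 0
        assert not set(a.tolist()) & set(b.tolist())

    def test_mass_equals_density_times_volume(self, cortical, trabecular):
        m = make_zygoma_arch(ArchSpec())
        from osteoimpact import lumped_mass

        masses = lumped_mass(m, {PHASE_CORTICAL: cortical, PHASE_TRABECULAR: trabecular})
        vols = m.element_volumes()
        expect = (
            cortical.elastic.density * vols[m.phase == PHASE_CORTICAL].sum()
            + trabecular.elastic.density * vols[m.phase == PHASE_TRABECULAR].sum()
        )
        assert masses.sum() == pytest.approx(expect, rel=1e-12)

    def test_mass_monotone_in_cortical_thickness(self):
        vols = []
        for t in (1.5, 1.75, 2.0):
            m = make_zygoma_arch(ArchSpec(cortical_thickness=t))
            vols.append(m.element_volumes().sum())
        assert vols[0] < vols[1] < vols[2]


class TestImpactorBuilder:
    def test_default_mass_exact(self):
        imp = make_impactor()
        assert units.tonne_to_kg(imp.mass) == 2.0
        assert imp.length == 200.0 and imp.radius == 20.0

    def test_speed_conversion(self):
        imp = make_impactor(speed_kmh=20.0)
        assert np.linalg.norm(imp.velocity) == pytest.approx(20000.0 / 3.6, rel=1e-12)
        assert np.linalg.norm(imp.velocity) == pytest.approx(5555.6, abs=0.1)

    def test_zero_speed_zero_velocity(self):
        imp = make_impactor(speed_kmh=0.0)
        np.testing.assert_array_equal(imp.velocity, 0.0)

    def test_equivalent_density_reported(self):
        imp = make_impactor()
        assert imp.equivalent_density == pytest.approx(imp.mass / (np.pi * 20.0**2 * 200.0))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_impactor(diameter=0.0)
        with pytest.raises(ValueError):
            make_impactor(length=-1.0)


class TestMeshValidityAndTie:
    def test_inverted_element_rejected(self):
        m = make_single_element(1.0)
        bad = Mesh(nodes=m.nodes, hexes=m.hexes[:, [4, 5, 6, 7, 0, 1, 2, 3]], phase=m.phase)
        with pytest.raises(MeshError):
            bad.validate()

    def test_out_of_range_connectivity_rejected(self):
        m = make_single_element(1.0)
        bad = Mesh(nodes=m.nodes, hexes=m.hexes + 5, phase=m.phase)
        with pytest.raises(MeshError):
            bad.validate()

    def _stacked_cubes(self, shift=0.0):
        a = make_single_element(1.0)
        b = make_single_element(1.0)
        nodes_b = b.nodes + np.array([0.0, 0.0, 1.0 + shift])
        nodes = np.vstack([a.nodes, nodes_b])
        hexes = np.vstack([a.hexes, b.hexes + a.n_nodes])
        sets = {
            "top_of_a": a.node_sets["z1"],
            "bottom_of_b": b.node_sets["z0"] + a.n_nodes,
        }
        return Mesh(nodes=nodes, hexes=hexes, phase=np.zeros(2, dtype=np.int64), node_sets=sets)

    def test_tie_merges_coincident_interface(self):
        m = self._stacked_cubes()
        tied = merge_tie(m, "top_of_a", "bottom_of_b", tolerance=1e-9)
        assert tied.n_nodes == 12  # 16 - 4 merged
        tied.validate()

    def test_tie_beyond_tolerance_errors(self):
        m = self._stacked_cubes(shift=0.2)
        with pytest.raises(MeshError):
            merge_tie(m, "top_of_a", "bottom_of_b", tolerance=1e-3)

    def test_tied_assembly_strain_free_under_translation(self, cortical):
        from osteoimpact.solver import ExplicitSolver

        tied = merge_tie(self._stacked_cubes(), "top_of_a", "bottom_of_b", tolerance=1e-9)
        s = ExplicitSolver(tied, {0: cortical}, damage=None, fixed_sets=())
        du = np.tile([0.1, -0.05, 0.02], (tied.n_nodes, 1))
        f = s.internal_forces(du, 1e-6)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_json_round_trip(self, tmp_path, plate_mesh):
        p = tmp_path / "mesh.json"
        plate_mesh.save(p)
        back = Mesh.load(p)
        np.testing.assert_allclose(back.nodes, plate_mesh.nodes)
        np.testing.assert_array_equal(back.hexes, plate_mesh.hexes)
        np.testing.assert_array_equal(back.phase, plate_mesh.phase)
        assert set(back.node_sets) == set(plate_mesh.node_sets)
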