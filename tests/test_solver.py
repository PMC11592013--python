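"""Explicit dynamics: mass, stable increments, stepping, conservation."""

import numpy as np
import pytest

from osteoimpact import Mesh, lumped_mass, make_single_element, mass_scale, stable_dt
from osteoimpact.geometry import _structured_hexes
from osteoimpact.solver import ExplicitSolver


def bar_mesh(nx, ny=2, nz=2, elem=1.0):
    xs = np.arange(nx + 1.0) * elem
    ys = np.arange(ny + 1.0) * elem
    zs = np.arange(nz + 1.0) * elem
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    return Mesh(nodes=nodes, hexes=_structured_hexes(nx, ny, nz))


def cube_to_tets(size=1.0):
    """Six-tet decomposition of a cube (for tet-path checks)."""
    m = make_single_element(size)
    n = m.hexes[0]
    tets = np.array(
        [
            [n[0], n[1], n[2], n[6]],
            [n[0], n[2], n[3], n[6]],
            [n[0], n[3], n[7], n[6]],
            [n[0], n[7], n[4], n[6]],
            [n[0], n[4], n[5], n[6]],
            [n[0], n[5], n[1], n[6]],
        ]
    )
    return Mesh(nodes=m.nodes, tets=tets, phase=np.zeros(6, dtype=np.int64))


class TestLumpedMass:
    def test_unit_cortical_cube_shares_mass_equally(self, cortical):
        m = make_single_element(10.0)
        masses = lumped_mass(m, {0: cortical})
        total_g = masses.sum() * 1e6  # tonne -> g
        assert total_g == pytest.approx(2.12, rel=1e-12)
        np.testing.assert_allclose(masses, masses[0])

    def test_two_disjoint_cubes_double(self, cortical):
        one = make_single_element(1.0)
        nodes = np.vstack([one.nodes, one.nodes + 10.0])
        m = Mesh(nodes=nodes, hexes=np.vstack([one.hexes, one.hexes + 8]), phase=np.zeros(2, dtype=np.int64))
        m1 = lumped_mass(one, {0: cortical}).sum()
        m2 = lumped_mass(m, {0: cortical}).sum()
        assert m2 == pytest.approx(2.0 * m1, rel=1e-14)

    def test_tet_mesh_total_mass_exact(self, cortical):
        m = cube_to_tets(1.7)
        masses = lumped_mass(m, {0: cortical})
        expect = cortical.elastic.density * m.element_volumes().sum()
        assert masses.sum() == pytest.approx(expect, rel=1e-12)


class TestStableDt:
    def test_cortical_mm_element_cfl(self, cortical):
        # 1 mm cortical cube: c_d ~ 2.95e6 mm/s -> dt ~ 3.4e-7 s
        m = make_single_element(1.0)
        per_elem, _ = stable_dt(m, {0: cortical})
        assert cortical.elastic.dilatational_wave_speed == pytest.approx(2.95e6, rel=0.01)
        assert per_elem[0] == pytest.approx(3.4e-7, rel=0.02)

    def test_halving_size_halves_dt(self, cortical):
        d1, _ = stable_dt(make_single_element(1.0), {0: cortical})
        d2, _ = stable_dt(make_single_element(0.5), {0: cortical})
        assert d2[0] == pytest.approx(0.5 * d1[0], rel=1e-12)

    def test_trabecular_slower_wave_larger_dt(self, cortical, trabecular):
        dc, _ = stable_dt(make_single_element(1.0), {0: cortical})
        m = make_single_element(1.0, phase=0)
        dtr, _ = stable_dt(m, {0: trabecular})
        assert dtr[0] > dc[0]


class TestMassScaling:
    def test_quadratic_factor(self, cortical):
        m = make_single_element(0.1)  # small element, tiny stable dt
        per_elem, _ = stable_dt(m, {0: cortical})
        target = 4.0 * per_elem[0]
        masses, report = mass_scale(m, {0: cortical}, dt_target=target, budget=1.0)
        base = lumped_mass(m, {0: cortical})
        np.testing.assert_allclose(masses / base, 16.0, rtol=1e-12)
        assert report["added_mass_fraction"] == pytest.approx(15.0, rel=1e-9)

    def test_already_stable_untouched(self, cortical):
        m = make_single_element(1.0)
        masses, report = mass_scale(m, {0: cortical}, dt_target=1e-8)
        np.testing.assert_allclose(masses, lumped_mass(m, {0: cortical}))
        assert report["added_mass_fraction"] == 0.0
        assert report["scaled_elements"].size == 0

    def test_post_scaling_global_dt_meets_target(self, cortical):
        # mixed element sizes: one fine slab in an otherwise uniform bar
        m = bar_mesh(6)
        m.nodes[m.nodes[:, 0] == 1.0, 0] = 0.25  # squeeze the first slab
        dt_elem, _ = stable_dt(m, {0: cortical})
        target = dt_elem.max() * 0.5
        _, report = mass_scale(m, {0: cortical}, dt_target=target, budget=1.0)
        scaled_dt = dt_elem * np.sqrt(report["element_factors"])
        assert scaled_dt.min() >= target * (1 - 1e-12)

    def test_budget_warning(self, cortical):
        m = make_single_element(0.1)
        per_elem, _ = stable_dt(m, {0: cortical})
        with pytest.warns(UserWarning, match="mass scaling"):
            mass_scale(m, {0: cortical}, dt_target=2 * per_elem[0], budget=0.01)


class TestStepping:
    def test_uniform_motion_exact(self, cortical):
        s = ExplicitSolver(make_single_element(1.0), {0: cortical}, damage=None, fixed_sets=())
        s.v[:] = [250.0, -100.0, 40.0]
        for _ in range(500):
            s.step()
        np.testing.assert_allclose(s.u, s.v * s.time, rtol=1e-9)
        assert np.abs(s.groups[0].stress).max() < 1e-10

    def test_internal_forces_zero_on_undeformed(self, cortical):
        s = ExplicitSolver(bar_mesh(3), {0: cortical}, damage=None, fixed_sets=())
        f = s.internal_forces(np.zeros((s.mesh.n_nodes, 3)), 1e-7)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_internal_forces_uniform_stretch_closed_form(self, cortical):
        """One elastic cube under homogeneous stretch: f = sigma * A on each face."""
        m = make_single_element(1.0)
        s = ExplicitSolver(m, {0: cortical}, damage=None, fixed_sets=())
        eps = 1e-5
        du = np.zeros((8, 3))
        du[m.nodes[:, 0] == 1.0, 0] = eps
        f = s.internal_forces(du, 1e-7)
        el = cortical.elastic
        sig_xx = (el.lame_lambda + 2 * el.shear_modulus) * eps
        sig_lat = el.lame_lambda * eps
        face = m.nodes[:, 0] == 1.0
        assert f[face, 0].sum() == pytest.approx(sig_xx * 1.0, rel=1e-8)
        back = m.nodes[:, 0] == 0.0
        assert f[back, 0].sum() == pytest.approx(-sig_xx * 1.0, rel=1e-8)
        top = m.nodes[:, 2] == 1.0
        assert f[top, 2].sum() == pytest.approx(sig_lat * 1.0, rel=1e-8)

    def test_rigid_translation_no_internal_force(self, cortical):
        s = ExplicitSolver(bar_mesh(4), {0: cortical}, damage=None, fixed_sets=())
        du = np.tile([0.3, 0.1, -0.2], (s.mesh.n_nodes, 1))
        f = s.internal_forces(du, 1e-7)
        np.testing.assert_allclose(f, 0.0, atol=1e-8)

    def test_axial_wave_speed(self, cortical):
        mesh = bar_mesh(40)
        s = ExplicitSolver(mesh, {0: cortical}, damage=None, fixed_sets=())
        struck = mesh.nodes[:, 0] < 0.5
        far = mesh.nodes[:, 0] > 39.5
        s.v[struck] = [1000.0, 0.0, 0.0]
        cd = cortical.elastic.dilatational_wave_speed
        arrival = None
        while s.time < 2.0 * 40.0 / cd:
            s.step()
            if np.abs(s.v[far, 0]).max() > 10.0:
                arrival = s.time
                break
        assert arrival is not None
        assert arrival == pytest.approx(40.0 / cd, rel=0.05)

    def test_two_body_impact_momentum_conserved(self, cortical):
        """Free block struck by the rigid impactor: total momentum within 1e-6."""
        from osteoimpact import ContactLaw, FrictionModel
        from osteoimpact.geometry import make_impactor

        m = bar_mesh(4, 4, 2)  # small free block
        imp = make_impactor(speed_kmh=10.0, aim=(2.0, 2.0, 2.0))
        imp.center = np.array([2.0, 2.0, 2.0 + 20.0 + 1.6])
        imp.velocity = np.array([0.0, 0.0, -2777.8])
        s = ExplicitSolver(
            m, {0: cortical}, damage=None, fixed_sets=(), impactor=imp,
            contact_law=ContactLaw(), friction=FrictionModel(),
        )
        p0 = s.momentum()
        for _ in range(600):
            s.step()
        p1 = s.momentum()
        scale = np.abs(p0).max()
        assert np.abs(p1 - p0).max() / scale < 1e-6
        # and the block actually picked up momentum from the impactor
        assert (s.masses[:, None] * s.v).sum(axis=0)[2] < -1e-9

    def test_free_vibration_energy_residual_small(self, cortical):
        mesh = bar_mesh(24)
        s = ExplicitSolver(mesh, {0: cortical}, damage=None, fixed_sets=())
        # smooth axial excitation dominated by the fundamental modes
        s.v[:, 0] = 500.0 * np.sin(np.pi * mesh.nodes[:, 0] / 24.0)
        for _ in range(3000):
            s.step()
        e0 = s.ledger.initial_total
        assert abs(s.ledger.residual()) / e0 < 0.02

    def test_excessive_dt_rejected(self, cortical):
        s = ExplicitSolver(make_single_element(1.0), {0: cortical}, damage=None, fixed_sets=())
        with pytest.raises(ValueError):
            s.step(dt=10.0 * s.dt)


class TestDeletionMechanics:
    def test_deleted_elements_carry_no_force(self, cortical, damage_card):
        s = ExplicitSolver(make_single_element(1.0), {0: cortical}, damage=damage_card, fixed_sets=())
        g = s.groups[0]
        g.damage.deleted[:] = True
        du = np.zeros((8, 3))
        du[s.mesh.nodes[:, 0] == 1.0, 0] = 0.01
        f = s.internal_forces(du, 1e-6)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)
        # irreversible even under further loading
        assert g.damage.deleted.all()
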