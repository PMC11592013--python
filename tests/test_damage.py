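"""Damage initiation, fracture-energy softening, deletion."""

import numpy as np
import pytest

from osteoimpact import DamageCard, apply_damage, onset_strain, trabecular_failure
from osteoimpact.damage import (
    DEFAULT_ONSET_TABLE,
    DamageState,
    DamageStateError,
    accumulate_initiation,
    evolve_damage,
    update_deletion,
)
from osteoimpact.materials import ConfigurationError
from osteoimpact.rigs import plastic_rate_onset_test, uniaxial_test


class TestOnsetStrain:
    @pytest.mark.parametrize("eps_on, _triax, rate", DEFAULT_ONSET_TABLE)
    def test_tabulated_rates_exact(self, damage_card, eps_on, _triax, rate):
        assert onset_strain(damage_card, rate) == eps_on

    def test_log_midpoint_interpolation(self, damage_card):
        # halfway between 1/s and 10/s in log10 space
        got = onset_strain(damage_card, 10.0**0.5)
        assert got == pytest.approx(0.5 * (0.0149 + 0.0123), abs=1e-6)

    def test_below_first_nonzero_rate_returns_quasi_static(self, damage_card):
        assert onset_strain(damage_card, 0.001) == 0.02

    def test_clamped_above_table(self, damage_card):
        assert onset_strain(damage_card, 5000.0) == 0.0024

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigurationError):
            DamageCard(onset_table=np.zeros((0, 3)))

    def test_increasing_onset_with_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            DamageCard(onset_table=[[0.01, 0.33, 0.0], [0.02, 0.33, 1.0]])


class TestInitiation:
    def test_zero_increment_leaves_omega(self, damage_card):
        st = DamageState(char_length=np.ones(1))
        accumulate_initiation(st, 0.0, 0.0, damage_card)
        assert st.omega[0] == 0.0

    def test_quasi_static_onset_at_two_percent(self, damage_card):
        st = DamageState(char_length=np.ones(1))
        accumulate_initiation(st, 0.02, 0.0, damage_card)
        assert st.omega[0] == pytest.approx(1.0)

    def test_increment_additivity(self, damage_card):
        a = DamageState(char_length=np.ones(1))
        accumulate_initiation(a, 0.02, 0.0, damage_card)
        b = DamageState(char_length=np.ones(1))
        accumulate_initiation(b, 0.01, 0.0, damage_card)
        accumulate_initiation(b, 0.01, 0.0, damage_card)
        assert a.omega[0] == pytest.approx(b.omega[0])

    def test_omega_monotone_under_random_loading(self, damage_card, rng):
        st = DamageState(char_length=np.ones(4))
        prev = st.omega.copy()
        for _ in range(50):
            accumulate_initiation(st, rng.uniform(0, 1e-3, 4), rng.uniform(0, 100, 4), damage_card)
            assert np.all(st.omega >= prev)
            prev = st.omega.copy()

    def test_onset_table_reproduced_by_rate_controlled_element(self, cortical, damage_card):
        for eps_on, _t, rate in DEFAULT_ONSET_TABLE:
            got = plastic_rate_onset_test(cortical, damage_card, rate)
            assert got == pytest.approx(eps_on, rel=1e-9)


class TestEvolution:
    def _initiated_state(self, sigma=100.0, le=1.0):
        st = DamageState(char_length=np.array([le]))
        st.omega[:] = 1.0
        st.sigma_y0_at_onset[:] = sigma
        return st

    def test_no_displacement_no_damage(self, damage_card):
        st = self._initiated_state()
        evolve_damage(st, 0.0, damage_card.fracture_energy)
        assert st.d[0] == 0.0

    def test_linear_law_midpoint(self):
        # u_f = 2G/sigma = 0.0308 mm at sigma = 100 MPa, G = 1.54 mJ/mm^2
        st = self._initiated_state(sigma=100.0, le=1.0)
        evolve_damage(st, 0.0154, 1.54)
        assert st.u_pl[0] == pytest.approx(0.0154)
        assert st.d[0] == pytest.approx(0.5)

    def test_softening_dissipates_fracture_energy(self):
        """Trapezoid integral of (1-d) sigma over u_pl equals G."""
        g_target = 1.54
        sigma = 100.0
        st = self._initiated_state(sigma=sigma, le=1.0)
        n = 2000
        du = (2 * g_target / sigma) / n
        work = 0.0
        d_prev = 0.0
        for _ in range(n):
            evolve_damage(st, du, g_target)
            work += 0.5 * ((1 - d_prev) + (1 - st.d[0])) * sigma * du
            d_prev = st.d[0]
        assert work == pytest.approx(g_target, rel=1e-3)

    def test_damage_monotone_and_capped(self, damage_card, rng):
        st = self._initiated_state()
        prev = 0.0
        for _ in range(200):
            evolve_damage(st, rng.uniform(0, 2e-3), damage_card.fracture_energy)
            assert prev <= st.d[0] <= 1.0
            prev = st.d[0]

    def test_missing_onset_stress_is_error(self, damage_card):
        st = DamageState(char_length=np.ones(1))
        st.omega[:] = 1.0  # initiated but no recorded stress
        with pytest.raises(DamageStateError):
            evolve_damage(st, 1e-3, damage_card.fracture_energy)


class TestApplyDamageAndDeletion:
    def test_degradation_endpoints_and_midpoint(self):
        s = np.array([[100.0, 0, 0, 0, 0, 0.0]])
        np.testing.assert_allclose(apply_damage(s, 0.0), s)
        np.testing.assert_allclose(apply_damage(s, 1.0), 0.0 * s)
        assert apply_damage(s, 0.5)[0, 0] == pytest.approx(50.0)

    def test_out_of_range_damage_rejected(self):
        with pytest.raises(DamageStateError):
            apply_damage(np.zeros((1, 6)), 1.5)

    def test_deletion_irreversible(self, damage_card):
        st = DamageState(char_length=np.ones(1))
        st.d[:] = 1.0
        update_deletion(st, damage_card)
        assert st.deleted[0]
        st.d[:] = 0.0  # even if d were reset, deletion persists
        update_deletion(st, damage_card)
        assert st.deleted[0]

    def test_trabecular_cap(self, damage_card):
        assert not trabecular_failure(0.05, damage_card)
        assert trabecular_failure(0.06, damage_card)
        assert trabecular_failure(0.10, damage_card)


class TestSingleElementFailure:
    def test_dissipation_mesh_size_independent(self, cortical, damage_card):
        """Pull-to-failure dissipates G per unit area for L_e in {0.5, 1, 2} mm."""
        g_ref = damage_card.fracture_energy
        for le in (0.5, 1.0, 2.0):
            res = uniaxial_test(cortical, 0.12, n_steps=3000, damage=damage_card, char_length=le)
            assert res.deleted_at_strain is not None
            assert res.post_onset_dissipation_per_area == pytest.approx(g_ref, rel=0.02)

    def test_infinite_fracture_energy_never_deletes(self, cortical, damage_card):
        card = DamageCard(
            onset_table=damage_card.onset_table,
            fracture_energy=1e12,
            trabecular_cap=damage_card.trabecular_cap,
        )
        res = uniaxial_test(cortical, 0.10, n_steps=800, damage=card)
        assert res.deleted_at_strain is None
        assert res.damage.max() < 1e-6
        # and the stress path reduces to plain plasticity (flat at the clamp value)
        assert res.stress[-1] == pytest.approx(cortical.hardening.points[-1, 1], rel=1e-3)

    def test_quasi_static_deletion_strain_near_three_percent(self, cortical, damage_card):
        """Total plastic strain at deletion ~3% at the study element size."""
        res = uniaxial_test(cortical, 0.12, n_steps=3000, damage=damage_card, char_length=1.5)
        assert res.deleted_at_strain is not None
        eps_pl_at_deletion = res.eps_pl[-1]
        assert eps_pl_at_deletion == pytest.approx(0.03, rel=0.15)
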