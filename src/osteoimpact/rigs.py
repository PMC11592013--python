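"""Single-element verification rigs.

These drive the constitutive and contact models through the canonical
verification loadings:

* displacement-controlled uniaxial tension of one element (homogeneous
  deformation, lateral faces stress-free — solved as the equivalent
  material-point path with the lateral strain iterated to zero lateral
  stress each step);
* block-on-cylinder steady sliding for the friction ratio.

They are used by the test suite and the verification CLI, and exercise the
same ``stress_update`` / damage / contact code paths as the full solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactLaw, FrictionModel, RigidImpactor, resolve_contact
from .damage import DamageCard, DamageState, onset_strain, smoothed_rate, update_deletion, evolve_damage
from .materials import MaterialCard, flow_stress, stress_update

__all__ = ["UniaxialResult", "uniaxial_test", "measure_elastic_modulus", "sliding_friction_test"]

QUASI_STATIC_RATE = 1.0e-12  # 1/s; Cowper-Symonds factor 1 to ~7 digits


@dataclass
class UniaxialResult:
    strain: np.ndarray  # total axial strain
    stress: np.ndarray  # applied (damage-degraded) axial stress, MPa
    eps_pl: np.ndarray
    omega: np.ndarray
    damage: np.ndarray
    rate_pl: np.ndarray  # smoothed plastic strain rate, 1/s
    deleted_at_strain: float | None
    onset_strain_observed: float | None  # eps_pl at omega crossing 1
    onset_rate_observed: float | None
    post_onset_dissipation_per_area: float  # mJ/mm^2 (plastic work * L_e after onset)

    @property
    def modulus(self) -> float:
        """Secant slope over the recorded path (useful below yield), MPa."""
        return float(self.stress[-1] / self.strain[-1])


def uniaxial_test(
    card: MaterialCard,
    total_strain: float,
    n_steps: int = 400,
    strain_rate: float | None = None,
    damage: DamageCard | None = None,
    char_length: float = 1.0,
    stop_on_deletion: bool = True,
) -> UniaxialResult:
    """Displacement-controlled single-element uniaxial tension.

    ``strain_rate`` (1/s) sets the time increment (``None`` means
    quasi-static); ``char_length`` is the element size entering the
    fracture-energy softening.  Lateral strains are iterated each increment
    so the lateral stress vanishes (free faces).
    """
    d_eps = total_strain / n_steps
    rate = strain_rate if strain_rate is not None else QUASI_STATIC_RATE
    dt = d_eps / rate

    stress = np.zeros((1, 6))
    eps_pl = np.zeros(1)
    state = DamageState(char_length=np.array([char_length]))
    dcard = damage

    eps_lat = 0.0
    slope = None
    lat_ratio = -card.elastic.poisson_ratio
    strain_hist = [0.0]
    stress_hist = [0.0]
    eps_pl_hist = [0.0]
    omega_hist = [0.0]
    d_hist = [0.0]
    rate_hist = [0.0]
    deleted_at = None
    onset_eps = None
    onset_rate = None
    dissipation = 0.0

    for i in range(n_steps):
        # Newton/secant on the lateral strain increment for zero lateral stress,
        # warm-started from the previous step's converged contraction ratio.
        dl = lat_ratio * d_eps
        for it in range(40):
            s_try, de_try, _ = stress_update(card, _incr(d_eps, dl), stress, eps_pl, dt)
            lat = s_try[0, 1]
            if abs(lat) < 1e-9 * max(1.0, abs(s_try[0, 0])):
                break
            if slope is None or it >= 2:
                h = max(1e-12, 1e-7 * max(abs(dl), 1e-4))
                s_h, _, _ = stress_update(card, _incr(d_eps, dl + h), stress, eps_pl, dt)
                slope = (s_h[0, 1] - lat) / h
            dl -= lat / slope
        lat_ratio = dl / d_eps
        stress, d_eps_pl, _ = stress_update(card, _incr(d_eps, dl), stress, eps_pl, dt)
        eps_pl = eps_pl + d_eps_pl
        eps_lat += dl

        factor = 1.0
        if dcard is not None:
            if card.phase == "cortical":
                r_s = smoothed_rate(state, d_eps_pl / dt, dcard.rate_smoothing)
                sig_flow = flow_stress(card, eps_pl, 0.0) * card.rate_law.factor(r_s)
                was = state.initiated.copy()
                state.omega = state.omega + d_eps_pl / onset_strain(dcard, r_s)
                crossed = state.initiated & ~was
                if crossed[0]:
                    state.sigma_y0_at_onset = np.where(crossed, sig_flow, state.sigma_y0_at_onset)
                    onset_eps = float(eps_pl[0])
                    onset_rate = float(r_s[0])
                evolve_damage(state, d_eps_pl, dcard.fracture_energy)
                update_deletion(state, dcard)
            else:
                from .damage import trabecular_failure

                state.deleted |= trabecular_failure(eps_pl, dcard)
            factor = float((1.0 - state.d[0]) * (not state.deleted[0]))

        if dcard is not None and state.initiated[0]:
            q = abs(stress[0, 0] - stress[0, 1])  # uniaxial effective stress
            dissipation += factor * q * float(d_eps_pl[0]) * char_length

        strain_hist.append((i + 1) * d_eps)
        stress_hist.append(factor * stress[0, 0])
        eps_pl_hist.append(float(eps_pl[0]))
        omega_hist.append(float(state.omega[0]))
        d_hist.append(float(state.d[0]))
        rate_hist.append(float(state.rate_ema[0]))

        if dcard is not None and state.deleted[0]:
            deleted_at = (i + 1) * d_eps
            if stop_on_deletion:
                break

    return UniaxialResult(
        strain=np.asarray(strain_hist),
        stress=np.asarray(stress_hist),
        eps_pl=np.asarray(eps_pl_hist),
        omega=np.asarray(omega_hist),
        damage=np.asarray(d_hist),
        rate_pl=np.asarray(rate_hist),
        deleted_at_strain=deleted_at,
        onset_strain_observed=onset_eps,
        onset_rate_observed=onset_rate,
        post_onset_dissipation_per_area=dissipation,
    )


def _incr(d_axial: float, d_lateral: float) -> np.ndarray:
    out = np.zeros((1, 6))
    out[0, 0] = d_axial
    out[0, 1] = d_lateral
    out[0, 2] = d_lateral
    return out


def plastic_rate_onset_test(
    card: MaterialCard,
    damage: DamageCard,
    eps_dot_pl: float,
    n_steps: int = 500,
) -> float:
    """Onset plastic strain observed under a prescribed constant plastic rate.

    The material point is driven in plastic-strain control (each increment
    adds ``eps_dot_pl * dt`` of equivalent plastic strain) through the full
    damage-accumulation path, and the omega = 1 crossing is located by
    linear interpolation between increments.  At a constant rate this
    recovers the tabulated onset strain for that rate.
    """
    target = 3.0 * onset_strain(damage, eps_dot_pl)
    d_eps = target / n_steps
    dt = d_eps / eps_dot_pl if eps_dot_pl > 0 else 1.0
    state = DamageState(char_length=np.array([1.0]))
    eps = 0.0
    prev_omega = 0.0
    for _ in range(n_steps):
        rate = d_eps / dt if eps_dot_pl > 0 else 0.0
        r_s = smoothed_rate(state, np.array([rate]), damage.rate_smoothing)
        state.omega = state.omega + d_eps / onset_strain(damage, r_s)
        eps += d_eps
        if state.omega[0] >= 1.0:
            # interpolate the crossing inside the last increment
            frac = (1.0 - prev_omega) / (state.omega[0] - prev_omega)
            return eps - d_eps + frac * d_eps
        prev_omega = float(state.omega[0])
    raise RuntimeError("omega never reached 1 within the prescribed strain range")


def measure_elastic_modulus(card: MaterialCard, strain: float = 1.0e-4, n_steps: int = 20) -> float:
    """Apparent Young's modulus (MPa) from the sub-yield uniaxial test."""
    res = uniaxial_test(card, strain, n_steps=n_steps)
    return res.modulus


def sliding_friction_test(
    law: ContactLaw | None = None,
    friction: FrictionModel | None = None,
    clearance: float = 0.5,
    drag_speed: float = 10.0,
    n_points: int = 4,
    n_steps: int = 10,
    dt: float = 1.0e-4,
) -> float:
    """Steady-sliding tangential/normal force ratio against the cylinder.

    A small block face (``n_points`` nodes of unit tributary area) is held
    at fixed clearance under the rigid cylinder and dragged along the
    cylinder axis at ``drag_speed`` (above the friction regularization
    velocity), and the mean |tangential| / |normal| resultant ratio over the
    steps is returned.
    """
    law = law if law is not None else ContactLaw()
    friction = friction if friction is not None else FrictionModel()
    imp = RigidImpactor(
        length=200.0,
        radius=20.0,
        mass=2.0e-3,
        center=np.zeros(3),
        axis=np.array([1.0, 0.0, 0.0]),
        velocity=np.zeros(3),
    )
    xs = np.linspace(-1.0, 1.0, n_points)
    pts = np.stack([xs, np.zeros(n_points), np.full(n_points, -(imp.radius + clearance))], axis=1)
    vel = np.tile([drag_speed, 0.0, 0.0], (n_points, 1))
    areas = np.ones(n_points)
    ratios = []
    for _ in range(n_steps):
        forces, reaction, info = resolve_contact(pts, vel, areas, imp, law, friction)
        fn = float(info["normal_force"].sum())
        ft = float(np.linalg.norm(info["tangential_force"].sum(axis=0)))
        ratios.append(ft / fn)
        pts = pts + vel * dt  # slide along the axis; clearance unchanged
    return float(np.mean(ratios))
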