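"""Rigid-impactor contact: exponential pressure-overclosure law + friction.

The skin between impactor and bone is not meshed; its force-transmitting
role is carried by an exponential penetration (pressure-overclosure) law
with clearance c0 = 1.5 mm (the average skin thickness over the cheekbone)
and p0 = 100 N/mm^2 at zero clearance:

    p(c) = 0                                   for c >= c0
    p(c) = p0 * (exp(1 - c/c0) - 1) / (e - 1)  for 0 <= c < c0
    p(c) = p0 - k0 * c                         for c < 0 (penetration)

with the penetration slope ``k0 = p'(0)`` continuing the exponential branch
linearly, keeping the contact stiffness bounded (and the explicit stable
time step unaffected).  Tangential traction is regularized Coulomb friction
capped at mu * p (mu = 0.2 between impactor and bone).

The impactor is a free-flying rigid cylinder advanced in translation by the
accumulated reaction; contact is node-to-analytic-surface against the exact
finite cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContactLaw",
    "FrictionModel",
    "RigidImpactor",
    "contact_pressure",
    "cylinder_clearance",
    "resolve_contact",
]


@dataclass(frozen=True)
class ContactLaw:
    """Exponential pressure-overclosure with linear penetration continuation."""

    c0: float = 1.5  # mm clearance at first force transmission
    p0: float = 100.0  # N/mm^2 at zero clearance

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.p0 <= 0:
            raise ValueError("contact law parameters must be positive")

    @property
    def penetration_stiffness(self) -> float:
        """|dp/dc| at c = 0 (N/mm^3), also the linear-branch slope."""
        return self.p0 * np.e / (self.c0 * (np.e - 1.0))

    def pressure(self, clearance):
        return contact_pressure(self, clearance)

    def potential(self, clearance):
        """Stored contact potential per unit area, integral of p dc up to c0 (mJ/mm^2)."""
        c = np.asarray(clearance, dtype=float)
        c0, p0 = self.c0, self.p0
        cc = np.clip(c, 0.0, c0)
        # integral of p over [cc, c0] for the exponential branch
        expo = (p0 / (np.e - 1.0)) * (c0 * (np.exp(1.0 - cc / c0) - 1.0) - (c0 - cc))
        pen = np.where(c < 0, -c * p0 + 0.5 * self.penetration_stiffness * c**2, 0.0)
        out = expo + pen
        return out if out.ndim else float(out)


def contact_pressure(law: ContactLaw, clearance):
    """Contact pressure (N/mm^2) at a signed clearance (mm)."""
    c = np.asarray(clearance, dtype=float)
    c0, p0 = law.c0, law.p0
    expo = p0 * (np.exp(1.0 - np.clip(c, 0.0, None) / c0) - 1.0) / (np.e - 1.0)
    p = np.where(c >= c0, 0.0, np.where(c >= 0.0, expo, p0 - law.penetration_stiffness * c))
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class FrictionModel:
    """Regularized Coulomb friction: traction ramps to the cap over v_reg."""

    mu: float = 0.2
    regularization_velocity: float = 1.0  # mm/s

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("friction coefficient must be non-negative")
        if self.regularization_velocity <= 0:
            raise ValueError("regularization velocity must be positive")


@dataclass
class RigidImpactor:
    """Finite rigid cylinder: pose, mass and free-flight state (translation)."""

    length: float  # mm
    radius: float  # mm
    mass: float  # tonne
    center: np.ndarray  # axis midpoint, mm
    axis: np.ndarray  # unit direction
    velocity: np.ndarray  # mm/s

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0 or self.mass <= 0:
            raise ValueError("impactor dimensions and mass must be positive")
        self.center = np.asarray(self.center, dtype=float).copy()
        axis = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            raise ValueError("impactor axis must be a nonzero vector")
        self.axis = axis / nrm
        self.velocity = np.asarray(self.velocity, dtype=float).copy()

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius**2 * self.length)

    @property
    def equivalent_density(self) -> float:
        """tonne/mm^3 implied by the assigned mass (reported, not used)."""
        return self.mass / self.volume

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * self.mass * float(self.velocity @ self.velocity)

    @property
    def momentum(self) -> np.ndarray:
        return self.mass * self.velocity

    def kick(self, force: np.ndarray, dt: float) -> None:
        """Leapfrog velocity update under the reaction force (position is
        advanced separately, at the start of the step)."""
        self.velocity = self.velocity + np.asarray(force, dtype=float) / self.mass * dt

    def clearance(self, points: np.ndarray):
        return cylinder_clearance(self, points)


def cylinder_clearance(impactor: RigidImpactor, points: np.ndarray):
    """Signed clearance to the finite cylinder surface, with outward normals.

    Positive outside, negative inside; end caps handled through the standard
    capped-cylinder signed distance (corner regions blend radially/axially).
    Returns ``(clearance (n,), normal (n, 3))``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - impactor.center
    z = rel @ impactor.axis
    radial = rel - z[:, None] * impactor.axis[None, :]
    r = np.linalg.norm(radial, axis=1)
    # Radial unit vector; arbitrary perpendicular for on-axis points.
    safe_r = np.where(r > 1e-12, r, 1.0)
    er = radial / safe_r[:, None]
    fallback = np.cross(impactor.axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(fallback) < 1e-9:
        fallback = np.cross(impactor.axis, [0.0, 1.0, 0.0])
    fallback = fallback / np.linalg.norm(fallback)
    er = np.where((r > 1e-12)[:, None], er, fallback[None, :])

    dr = r - impactor.radius
    dz = np.abs(z) - impactor.length / 2.0
    ez = np.sign(z)[:, None] * impactor.axis[None, :]

    outside_r = dr > 0
    outside_z = dz > 0
    corner = outside_r & outside_z
    d_corner = np.sqrt(np.where(corner, dr**2 + dz**2, 1.0))

    clearance = np.where(
        corner,
        np.sqrt(np.maximum(dr, 0.0) ** 2 + np.maximum(dz, 0.0) ** 2),
        np.where(outside_z, dz, np.where(outside_r, dr, np.maximum(dr, dz))),
    )
    normal = np.where(
        corner[:, None],
        (np.maximum(dr, 0.0)[:, None] * er + np.maximum(dz, 0.0)[:, None] * ez) / d_corner[:, None],
        np.where(
            outside_z[:, None],
            ez,
            np.where(outside_r[:, None] | (dr >= dz)[:, None], er, ez),
        ),
    )
    if np.asarray(points).ndim == 1:
        return float(clearance[0]), normal[0]
    return clearance, normal


def resolve_contact(
    points: np.ndarray,
    velocities: np.ndarray,
    areas: np.ndarray,
    impactor: RigidImpactor,
    law: ContactLaw,
    friction: FrictionModel | None = None,
    masses: np.ndarray | None = None,
    dt: float | None = None,
):
    """Nodal contact forces against the rigid cylinder and the exact reaction.

    ``points``/``velocities``/``areas`` describe the active surface nodes
    (tributary areas from the alive exterior faces).  Normal force per node
    is ``p(clearance) * area`` along the outward cylinder normal; tangential
    force is regularized Coulomb against the rigid-body velocity.  The
    impactor reaction is the exact negative resultant, so contact conserves
    linear momentum to round-off.

    Returns ``(forces (n, 3), reaction (3,), info dict)``; ``info`` carries
    the normal/friction work split inputs (normal and tangential force
    arrays, clearances).
    """
    pts = np.atleast_2d(points)
    if np.any(np.asarray(areas) <= 0):
        raise ValueError("non-positive tributary area in the contact surface")
    clearance, normal = cylinder_clearance(impactor, pts)
    p = contact_pressure(law, clearance)
    fn_mag = p * np.asarray(areas)
    if masses is not None and dt is not None:
        pen = clearance < 0
        if np.any(pen):
            # Impulse limit on the penetration branch: a node freshly exposed
            # by element deletion can sit deep inside the cylinder, and the
            # pre-compressed penalty spring would launch it with energy the
            # impactor never supplied. Beyond zero clearance the force may
            # not exceed the larger of the zero-clearance spring force and
            # the impulse that sweeps the node along with the surface.
            vel2 = np.atleast_2d(velocities)
            v_push = ((impactor.velocity[None, :] - vel2) * normal).sum(axis=1)
            f_static = law.p0 * np.asarray(areas)
            f_sweep = 0.5 * np.asarray(masses) * np.maximum(v_push, 0.0) / dt
            fn_mag = np.where(pen, np.minimum(fn_mag, np.maximum(f_static, f_sweep)), fn_mag)
    forces = fn_mag[:, None] * normal

    ft = np.zeros_like(forces)
    if friction is not None and friction.mu > 0:
        vel = np.atleast_2d(velocities)
        vrel = vel - impactor.velocity[None, :]
        vt = vrel - (vrel * normal).sum(axis=1)[:, None] * normal
        vt_mag = np.linalg.norm(vt, axis=1)
        active = (fn_mag > 0) & (vt_mag > 1e-15)
        scale = np.minimum(vt_mag / friction.regularization_velocity, 1.0)
        ft_mag = friction.mu * fn_mag * scale
        if masses is not None and dt is not None:
            # Momentum-consistent cap: the traction may not exceed the force
            # that would cancel the relative slip of the node within one
            # explicit step (half of it, for the leapfrog half-step lag).
            # Uncapped regularized Coulomb chatters around the stick state
            # and pumps energy into surface vibration.
            ft_mag = np.minimum(ft_mag, 0.5 * np.asarray(masses) * vt_mag / dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_hat = np.where(active[:, None], vt / np.where(vt_mag > 1e-15, vt_mag, 1.0)[:, None], 0.0)
        ft = -ft_mag[:, None] * t_hat
        forces = forces + ft

    reaction = -forces.sum(axis=0)
    info = {
        "clearance": clearance,
        "normal_force": fn_mag,
        "tangential_force": ft,
        "normal": normal,
    }
    return forces, reaction, info
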