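"""Bone constitutive behaviour.

Cortical and trabecular (cancellous) bone are modelled as isotropic
linear-elastic / multilinear J2-plastic solids.  Cortical bone is strain-rate
sensitive through the Cowper-Symonds overstress law

    eps_dot_pl = D * (R - 1)**n        <=>      R = 1 + (eps_dot_pl / D)**(1/n)

where ``R`` scales the whole quasi-static hardening curve.  Trabecular bone is
rate independent (its rate sensitivity has negligible influence on the
fracture outcome because it fails secondarily, after the cortical shell).

Stress and strain use Voigt order ``[xx, yy, zz, xy, yz, zx]`` with
engineering shear strains.  Stress is MPa, density tonne/mm^3 (see
:mod:`osteoimpact.units`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import units

__all__ = [
    "ElasticConstants",
    "HardeningCurve",
    "RateLaw",
    "MaterialCard",
    "rate_factor",
    "flow_stress",
    "stress_update",
    "cortical_card",
    "trabecular_card",
    "CORTICAL_RATE_D",
    "CORTICAL_RATE_N",
]

# Cowper-Symonds constants for cortical bone (THUMS calibration).
CORTICAL_RATE_D = 360.7  # 1/s
CORTICAL_RATE_N = 4.61


class ConfigurationError(ValueError):
    """Invalid material/damage card configuration."""


@dataclass(frozen=True)
class ElasticConstants:
    """Isotropic elastic constants in internal units (MPa, tonne/mm^3)."""

    young_modulus: float
    poisson_ratio: float
    density: float

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ConfigurationError("young_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ConfigurationError("poisson_ratio must lie in [0, 0.5)")
        if not self.density > 0:
            raise ConfigurationError("density must be positive")

    @classmethod
    def from_engineering(cls, young_gpa: float, poisson: float, density_g_cm3: float) -> "ElasticConstants":
        """Build from the units material tables are printed in (GPa, g/cm^3)."""
        return cls(
            young_modulus=units.gpa_to_mpa(young_gpa),
            poisson_ratio=poisson,
            density=units.g_cm3_to_internal(density_g_cm3),
        )

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def bulk_modulus(self) -> float:
        return self.young_modulus / (3.0 * (1.0 - 2.0 * self.poisson_ratio))

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def dilatational_wave_speed(self) -> float:
        """Longitudinal (P-wave) speed in mm/s; sets the explicit stable dt."""
        e, nu, rho = self.young_modulus, self.poisson_ratio, self.density
        return float(np.sqrt(e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * rho)))

    def stiffness_matrix(self) -> np.ndarray:
        """6x6 Voigt stiffness (engineering shear convention)."""
        lam, mu = self.lame_lambda, self.shear_modulus
        c = np.zeros((6, 6))
        c[:3, :3] = lam
        c[np.diag_indices(3)] += 2.0 * mu
        c[3, 3] = c[4, 4] = c[5, 5] = mu
        return c


@dataclass(frozen=True)
class HardeningCurve:
    """Quasi-static true-stress vs equivalent-plastic-strain table.

    The first abscissa must be 0 (initial yield); stresses may not soften —
    all softening enters through the damage model.
    """

    points: np.ndarray  # (n, 2): [eps_pl, sigma_MPa]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ConfigurationError("hardening curve needs an (n, 2) table")
        if pts[0, 0] != 0.0:
            raise ConfigurationError("hardening curve must start at eps_pl = 0")
        if pts.shape[0] > 1 and not np.all(np.diff(pts[:, 0]) > 0):
            raise ConfigurationError("hardening strains must strictly increase")
        if np.any(pts[:, 1] <= 0):
            raise ConfigurationError("hardening stresses must be positive")
        if pts.shape[0] > 1 and np.any(np.diff(pts[:, 1]) < 0):
            raise ConfigurationError("base hardening curve may not soften")
        object.__setattr__(self, "points", pts)

    @property
    def initial_yield(self) -> float:
        return float(self.points[0, 1])

    def stress(self, eps_pl):
        """Piecewise-linear interpolation, clamped at the last point."""
        pts = self.points
        return np.interp(eps_pl, pts[:, 0], pts[:, 1])


@dataclass(frozen=True)
class RateLaw:
    """Cowper-Symonds dynamic overstress factor."""

    D: float = CORTICAL_RATE_D
    n: float = CORTICAL_RATE_N
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ConfigurationError("Cowper-Symonds D must be positive")
        if not self.n > 0:
            raise ConfigurationError("Cowper-Symonds n must be positive")

    def factor(self, eps_dot_pl):
        return rate_factor(self, eps_dot_pl)


def rate_factor(rate_law: RateLaw, eps_dot_pl):
    """Dynamic scale factor R >= 1.

    ``R = 1 + (eps_dot_pl / D)**(1/n)``; exactly 1 at zero rate or when the
    law is disabled.  Accepts scalars or arrays; negative rates are a domain
    error.
    """
    rate = np.asarray(eps_dot_pl, dtype=float)
    if np.any(rate < 0):
        raise ValueError("plastic strain rate must be non-negative")
    if not rate_law.enabled:
        return np.ones_like(rate) if rate.ndim else 1.0
    r = 1.0 + (rate / rate_law.D) ** (1.0 / rate_law.n)
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class MaterialCard:
    """One bone phase: elasticity + hardening + rate law."""

    name: str
    elastic: ElasticConstants
    hardening: HardeningCurve
    rate_law: RateLaw
    phase: str  # "cortical" | "trabecular"

    def __post_init__(self) -> None:
        if self.phase not in ("cortical", "trabecular"):
            raise ConfigurationError(f"unknown bone phase {self.phase!r}")
        if self.phase == "trabecular" and self.rate_law.enabled:
            raise ConfigurationError("trabecular cards must have the rate law disabled")

    def to_dict(self) -> dict:
        """Interface serialization (GPa, g/cm^3, as material tables print them)."""
        return {
            "name": self.name,
            "phase": self.phase,
            "E_GPa": units.mpa_to_gpa(self.elastic.young_modulus),
            "nu": self.elastic.poisson_ratio,
            "rho_g_cm3": units.internal_to_g_cm3(self.elastic.density),
            "hardening": [[float(e), float(s)] for e, s in self.hardening.points],
            "cowper_symonds": {
                "D": self.rate_law.D,
                "n": self.rate_law.n,
                "enabled": self.rate_law.enabled,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialCard":
        cs = d.get("cowper_symonds", {})
        return cls(
            name=d["name"],
            elastic=ElasticConstants.from_engineering(d["E_GPa"], d["nu"], d["rho_g_cm3"]),
            hardening=HardeningCurve(np.asarray(d["hardening"], dtype=float)),
            rate_law=RateLaw(
                D=cs.get("D", CORTICAL_RATE_D),
                n=cs.get("n", CORTICAL_RATE_N),
                enabled=cs.get("enabled", d.get("phase") == "cortical"),
            ),
            phase=d["phase"],
        )


def flow_stress(card: MaterialCard, eps_pl, eps_dot_pl=0.0):
    """Rate-scaled yield stress at a given plastic strain (MPa).

    The whole quasi-static curve is multiplied by the Cowper-Symonds factor
    (standard overstress composition); trabecular cards are rate independent.
    """
    eps = np.asarray(eps_pl, dtype=float)
    if np.any(eps < 0):
        raise ValueError("plastic strain must be non-negative")
    sigma = card.hardening.stress(eps) * rate_factor(card.rate_law, eps_dot_pl)
    return sigma if np.ndim(sigma) else float(sigma)


# ---------------------------------------------------------------------------
# Radial-return stress integration (vectorized over integration points)
# ---------------------------------------------------------------------------

_VOIGT_DEV_WEIGHT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def von_mises_voigt(stress: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress of Voigt stresses, shape (..., 6)."""
    s = np.asarray(stress, dtype=float)
    a, b, c = s[..., 0], s[..., 1], s[..., 2]
    t2 = s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2
    return np.sqrt(0.5 * ((a - b) ** 2 + (b - c) ** 2 + (c - a) ** 2) + 3.0 * t2)


def stress_update(
    card: MaterialCard,
    dstrain: np.ndarray,
    stress: np.ndarray,
    eps_pl: np.ndarray,
    dt: float,
    spin: np.ndarray | None = None,
    bisect_iters: int = 60,
):
    """Advance the stress state of one batch of integration points.

    Elastic predictor + J2 radial return onto the rate-scaled yield surface.
    The plastic rate entering the Cowper-Symonds factor is the implicit
    ``delta_eps_pl / dt`` of the same step, solved by bisection (the residual
    is monotone in the plastic multiplier, so bisection is unconditionally
    robust).

    Parameters
    ----------
    dstrain : (n, 6) Voigt strain increments (engineering shear).
    stress : (n, 6) Voigt stresses at the start of the step (modified copy
        returned, input untouched).
    eps_pl : (n,) equivalent plastic strains.
    dt : time increment (s), > 0.
    spin : optional (n, 3, 3) skew spin increments W*dt; when given, the
        incoming stress is rotated by the Cayley transform
        ``R = (I - W/2)^-1 (I + W/2)`` (exactly orthogonal) before the
        constitutive update, giving incremental objectivity.

    Returns
    -------
    (new_stress (n, 6), delta_eps_pl (n,), eps_dot_pl (n,))
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    dstrain = np.atleast_2d(np.asarray(dstrain, dtype=float))
    stress = np.atleast_2d(np.asarray(stress, dtype=float)).copy()
    eps_pl = np.atleast_1d(np.asarray(eps_pl, dtype=float))
    if not (np.all(np.isfinite(dstrain)) and np.all(np.isfinite(stress))):
        bad = np.unique(
            np.concatenate(
                [
                    np.nonzero(~np.isfinite(dstrain).all(axis=1))[0],
                    np.nonzero(~np.isfinite(stress).all(axis=1))[0],
                ]
            )
        )
        raise FloatingPointError(f"non-finite stress/strain at integration points {bad[:10].tolist()}")

    if spin is not None:
        w = np.abs(np.asarray(spin)).max(axis=(-2, -1))
        rot = w > 1e-8  # smaller per-step rotations are below stress resolution
        if np.all(rot):
            stress = _rotate_voigt(stress, spin)
        elif np.any(rot):
            stress[rot] = _rotate_voigt(stress[rot], np.asarray(spin)[rot])

    el = card.elastic
    lam, mu = el.lame_lambda, el.shear_modulus

    # Elastic predictor.
    tr = dstrain[:, :3].sum(axis=1)
    stress[:, :3] += lam * tr[:, None] + 2.0 * mu * dstrain[:, :3]
    stress[:, 3:] += mu * dstrain[:, 3:]

    q_trial = von_mises_voigt(stress)
    sig_y0 = flow_stress(card, eps_pl, 0.0)
    yielding = q_trial > sig_y0 * (1.0 + 1e-12)

    d_eps = np.zeros(eps_pl.shape)
    rate = np.zeros(eps_pl.shape)
    if np.any(yielding):
        idx = np.nonzero(yielding)[0]
        qt = q_trial[idx]
        ep0 = eps_pl[idx]
        curve = card.hardening
        rlaw = card.rate_law

        if not rlaw.enabled and curve.points.shape[0] <= 2:
            # Rate-free linear hardening: the return has a closed form.
            h_mod = 0.0
            if curve.points.shape[0] == 2:
                (e0c, s0c), (e1c, s1c) = curve.points
                h_mod = (s1c - s0c) / (e1c - e0c)
            dl = (qt - curve.stress(ep0)) / (3.0 * mu + h_mod)
            # clamp handling: beyond the last curve point hardening is flat
            if h_mod > 0:
                over = ep0 + dl > curve.points[-1, 0]
                if np.any(over):
                    dl_flat = (qt - curve.points[-1, 1]) / (3.0 * mu)
                    dl = np.where(over, dl_flat, dl)
            dl = np.maximum(dl, 0.0)
            return _finish_return(stress, idx, qt, dl, mu, eps_pl, d_eps, rate, dt)

        lo = np.zeros(qt.shape)
        hi = qt / (3.0 * mu)
        for _ in range(bisect_iters):
            mid = 0.5 * (lo + hi)
            sig = curve.stress(ep0 + mid) * rate_factor(rlaw, mid / dt)
            res = qt - 3.0 * mu * mid - sig
            take = res > 0
            lo = np.where(take, mid, lo)
            hi = np.where(take, hi, mid)
            if np.max(hi - lo) <= 1e-8 * np.max(hi):
                break
        dl = 0.5 * (lo + hi)
        return _finish_return(stress, idx, qt, dl, mu, eps_pl, d_eps, rate, dt)

    return stress, d_eps, rate


def _finish_return(stress, idx, qt, dl, mu, eps_pl, d_eps, rate, dt):
    """Scale the trial deviator back to the yield surface (radial return)."""
    mean = stress[idx, :3].mean(axis=1)
    scale = 1.0 - 3.0 * mu * dl / qt
    stress[idx, :3] = (stress[idx, :3] - mean[:, None]) * scale[:, None] + mean[:, None]
    stress[idx, 3:] *= scale[:, None]
    d_eps[idx] = dl
    rate[idx] = dl / dt
    return stress, d_eps, rate


def _rotate_voigt(stress: np.ndarray, spin: np.ndarray) -> np.ndarray:
    """Rotate Voigt stresses by the Cayley transform of skew increments.

    ``R = (I - W/2)^{-1} (I + W/2)`` is exactly orthogonal for skew ``W``;
    for a 3x3 skew it has the closed form ``R = I + 2 (A + a a^T - a^2 I) /
    (1 + a^2)`` with ``A = W/2`` and axis vector ``a`` of ``A``, so a pure
    rotation preserves the stress invariants to machine precision.
    """
    w = np.asarray(spin, dtype=float)
    single = w.ndim == 2
    if single:
        w = w[None]
    stress = np.atleast_2d(stress)
    # axis components of A = W/2:  A = [[0,-a3,a2],[a3,0,-a1],[-a2,a1,0]]
    a1 = 0.5 * w[..., 2, 1]
    a2 = 0.5 * w[..., 0, 2]
    a3 = 0.5 * w[..., 1, 0]
    asq = a1 * a1 + a2 * a2 + a3 * a3
    f = 2.0 / (1.0 + asq)
    r00 = 1 + f * (a1 * a1 - asq)
    r01 = f * (a1 * a2 - a3)
    r02 = f * (a1 * a3 + a2)
    r10 = f * (a1 * a2 + a3)
    r11 = 1 + f * (a2 * a2 - asq)
    r12 = f * (a2 * a3 - a1)
    r20 = f * (a1 * a3 - a2)
    r21 = f * (a2 * a3 + a1)
    r22 = 1 + f * (a3 * a3 - asq)
    sxx, syy, szz, sxy, syz, szx = (stress[..., i] for i in range(6))
    # m = R S, then sigma' = m R^T, expanded componentwise
    m00 = r00 * sxx + r01 * sxy + r02 * szx
    m01 = r00 * sxy + r01 * syy + r02 * syz
    m02 = r00 * szx + r01 * syz + r02 * szz
    m10 = r10 * sxx + r11 * sxy + r12 * szx
    m11 = r10 * sxy + r11 * syy + r12 * syz
    m12 = r10 * szx + r11 * syz + r12 * szz
    m20 = r20 * sxx + r21 * sxy + r22 * szx
    m21 = r20 * sxy + r21 * syy + r22 * syz
    m22 = r20 * szx + r21 * syz + r22 * szz
    out = np.empty_like(stress)
    out[..., 0] = m00 * r00 + m01 * r01 + m02 * r02
    out[..., 1] = m10 * r10 + m11 * r11 + m12 * r12
    out[..., 2] = m20 * r20 + m21 * r21 + m22 * r22
    out[..., 3] = m00 * r10 + m01 * r11 + m02 * r12
    out[..., 4] = m10 * r20 + m11 * r21 + m12 * r22
    out[..., 5] = m20 * r00 + m21 * r01 + m22 * r02
    return out[0] if single else out


def _voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(v)
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = v[..., 0], v[..., 1], v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4]
    t[..., 2, 0] = t[..., 0, 2] = v[..., 5]
    return t


def _tensor_to_voigt(t: np.ndarray) -> np.ndarray:
    return np.stack(
        [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2], t[..., 0, 1], t[..., 1, 2], t[..., 2, 0]],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# Default type II bone cards
# ---------------------------------------------------------------------------
#
# The elastic constants are the type II bone values (cortical E = 13.7 GPa,
# cancellous E = 5.5 GPa, nu = 0.3, rho = 2.12 g/cm^3).  The hardening tables
# are calibration defaults chosen to be consistent with published cortical
# bone strength and the damage-onset strains: cortical yield 110 MPa rising
# linearly to 180 MPa at 2% plastic strain (so the rate-1000/s dynamic curve
# peaks near 250 MPa), trabecular yield 30 MPa, flat.  Both are fully
# overridable through the card dictionaries.

_DEFAULT_CORTICAL_HARDENING = [[0.0, 110.0], [0.02, 180.0]]
_DEFAULT_TRABECULAR_HARDENING = [[0.0, 30.0], [0.06, 30.0]]


def cortical_card(
    young_gpa: float = 13.7,
    poisson: float = 0.3,
    density_g_cm3: float = 2.12,
    hardening: Sequence[Sequence[float]] | None = None,
    rate_law: RateLaw | None = None,
) -> MaterialCard:
    """Default type II cortical bone card."""
    return MaterialCard(
        name="cortical",
        elastic=ElasticConstants.from_engineering(young_gpa, poisson, density_g_cm3),
        hardening=HardeningCurve(np.asarray(hardening if hardening is not None else _DEFAULT_CORTICAL_HARDENING)),
        rate_law=rate_law if rate_law is not None else RateLaw(),
        phase="cortical",
    )


def trabecular_card(
    young_gpa: float = 5.5,
    poisson: float = 0.3,
    density_g_cm3: float = 2.12,
    hardening: Sequence[Sequence[float]] | None = None,
) -> MaterialCard:
    """Default type II trabecular (cancellous) bone card; rate independent."""
    return MaterialCard(
        name="trabecular",
        elastic=ElasticConstants.from_engineering(young_gpa, poisson, density_g_cm3),
        hardening=HardeningCurve(
            np.asarray(hardening if hardening is not None else _DEFAULT_TRABECULAR_HARDENING)
        ),
        rate_law=RateLaw(enabled=False),
        phase="trabecular",
    )
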