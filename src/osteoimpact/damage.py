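"""Ductile damage initiation, fracture-energy softening and element deletion.

Damage initiation for cortical bone follows a ductile-rupture criterion: an
initiation measure (the field solvers label DUCTCRIT)

    omega = sum( delta_eps_pl / eps_onset(rate) )

accumulates plastic strain weighted by a rate-dependent onset strain taken
from a tabulated rupture-deformation table (onset strain falls from 0.02
quasi-statically to 0.0024 at 1000/s; a single triaxiality -p/q = 0.33,
uniaxial tension, is tabulated and triaxiality dependence is therefore
collapsed).  Initiation is declared at omega >= 1.

After initiation a scalar damage variable ``d`` grows linearly in the
effective plastic displacement ``u_pl = L_e * eps_pl`` up to

    u_f = 2 G / sigma_y0,      G = 1.54 mJ/mm^2,

which makes the softening dissipation per unit fractured area equal to G
independent of the element size ``L_e`` (fracture-energy regularization).
Stress is degraded by ``(1 - d)`` and the element is deleted at d >= 0.99.

Trabecular bone fails by a simple rate-independent cap on equivalent plastic
strain (default 0.06, i.e. twice the 3% cortical failure deformation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import ConfigurationError

__all__ = [
    "DamageCard",
    "DamageState",
    "onset_strain",
    "accumulate_initiation",
    "evolve_damage",
    "apply_damage",
    "trabecular_failure",
    "DEFAULT_ONSET_TABLE",
    "FRACTURE_ENERGY_DEFAULT",
]

# Rupture-deformation table for cortical bone: rows of
# (onset equivalent plastic strain, triaxiality -p/q, plastic strain rate 1/s).
DEFAULT_ONSET_TABLE = [
    [0.02, 0.33, 0.0],
    [0.02, 0.33, 0.01],
    [0.0175, 0.33, 0.1],
    [0.0149, 0.33, 1.0],
    [0.0123, 0.33, 10.0],
    [0.0072, 0.33, 100.0],
    [0.0024, 0.33, 1000.0],
]

FRACTURE_ENERGY_DEFAULT = 1.54  # mJ/mm^2


class DamageStateError(RuntimeError):
    """Inconsistent damage state (e.g. evolution before initiation)."""


@dataclass(frozen=True)
class DamageCard:
    """Damage parameters for one simulation (cortical onset table + caps)."""

    onset_table: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_ONSET_TABLE))
    fracture_energy: float = FRACTURE_ENERGY_DEFAULT  # mJ/mm^2
    trabecular_cap: float = 0.06
    deletion_threshold: float = 0.99
    rate_smoothing: float = 0.1  # EMA weight; ~10-step memory

    def __post_init__(self) -> None:
        table = np.asarray(self.onset_table, dtype=float)
        if table.ndim != 2 or table.shape[1] != 3 or table.shape[0] < 1:
            raise ConfigurationError("onset table needs rows (eps_onset, -p/q, rate)")
        if np.any(table[:, 0] <= 0):
            raise ConfigurationError("onset strains must be positive")
        if np.any(np.diff(table[:, 0]) > 0):
            raise ConfigurationError("onset strains must be non-increasing with rate")
        if np.any(np.diff(table[:, 2]) <= 0):
            raise ConfigurationError("onset-table rates must strictly increase")
        if not np.allclose(table[:, 1], table[0, 1]):
            raise ConfigurationError("all onset rows must share one triaxiality")
        if not self.fracture_energy > 0:
            raise ConfigurationError("fracture energy must be positive")
        if not self.trabecular_cap > 0:
            raise ConfigurationError("trabecular cap must be positive")
        if not (0 < self.deletion_threshold <= 1):
            raise ConfigurationError("deletion threshold must lie in (0, 1]")
        object.__setattr__(self, "onset_table", table)

    @property
    def triaxiality(self) -> float:
        return float(self.onset_table[0, 1])

    def to_dict(self) -> dict:
        return {
            "onset_table": self.onset_table.tolist(),
            "G_mJ_per_mm2": self.fracture_energy,
            "trabecular_cap": self.trabecular_cap,
            "deletion_threshold": self.deletion_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DamageCard":
        return cls(
            onset_table=np.asarray(d.get("onset_table", DEFAULT_ONSET_TABLE)),
            fracture_energy=d.get("G_mJ_per_mm2", FRACTURE_ENERGY_DEFAULT),
            trabecular_cap=d.get("trabecular_cap", 0.06),
            deletion_threshold=d.get("deletion_threshold", 0.99),
        )


def onset_strain(card: DamageCard, eps_dot_pl):
    """Damage-onset plastic strain at a given rate.

    Piecewise linear in log10(rate) between the tabulated nonzero rates,
    clamped at both ends; any rate at or below the first nonzero tabulated
    rate returns the quasi-static value.
    """
    rate = np.asarray(eps_dot_pl, dtype=float)
    if np.any(rate < 0):
        raise ValueError("plastic strain rate must be non-negative")
    table = card.onset_table
    pos = table[table[:, 2] > 0]
    if pos.shape[0] == 0:
        out = np.full(rate.shape, table[0, 0])
        return out if out.ndim else float(out)
    log_r = np.log10(np.maximum(rate, pos[0, 2]))
    out = np.interp(log_r, np.log10(pos[:, 2]), pos[:, 0])
    out = np.where(rate <= pos[0, 2], table[0, 0], out)
    return out if out.ndim else float(out)


@dataclass
class DamageState:
    """Per-element damage state arrays (scalars broadcast for n = 1 rigs).

    ``omega`` is the initiation measure (the DUCTCRIT analogue), ``d`` the
    stiffness-degradation variable, ``u_pl`` the post-initiation effective
    plastic displacement, ``char_length`` the element characteristic length
    L_e (mm) and ``sigma_y0_at_onset`` the flow stress recorded at the moment
    omega crossed 1 (it sets the failure displacement u_f = 2 G / sigma_y0).
    """

    char_length: np.ndarray
    omega: np.ndarray = None
    d: np.ndarray = None
    u_pl: np.ndarray = None
    deleted: np.ndarray = None
    sigma_y0_at_onset: np.ndarray = None
    rate_ema: np.ndarray = None
    _rate_seen: np.ndarray = None

    def __post_init__(self) -> None:
        self.char_length = np.atleast_1d(np.asarray(self.char_length, dtype=float))
        n = self.char_length.shape[0]
        if self.omega is None:
            self.omega = np.zeros(n)
        if self.d is None:
            self.d = np.zeros(n)
        if self.u_pl is None:
            self.u_pl = np.zeros(n)
        if self.deleted is None:
            self.deleted = np.zeros(n, dtype=bool)
        if self.sigma_y0_at_onset is None:
            self.sigma_y0_at_onset = np.zeros(n)
        if self.rate_ema is None:
            self.rate_ema = np.zeros(n)
        if self._rate_seen is None:
            self._rate_seen = np.zeros(n, dtype=bool)

    @property
    def n(self) -> int:
        return self.char_length.shape[0]

    @property
    def initiated(self) -> np.ndarray:
        return self.omega >= 1.0


def smoothed_rate(state: DamageState, eps_dot_pl: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average of the plastic strain rate.

    The EMA is seeded with the first observed nonzero-plastic-step rate (so a
    constant-rate test sees the exact rate from the first increment) and then
    relaxed with weight ``alpha`` per step to suppress step-to-step noise in
    the onset-strain lookup.
    """
    rate = np.asarray(eps_dot_pl, dtype=float)
    active = rate > 0
    fresh = active & ~state._rate_seen
    state.rate_ema = np.where(
        fresh, rate, np.where(active, (1 - alpha) * state.rate_ema + alpha * rate, state.rate_ema)
    )
    state._rate_seen |= active
    return state.rate_ema


def accumulate_initiation(
    state: DamageState,
    delta_eps_pl,
    eps_dot_pl,
    card: DamageCard,
    sigma_flow=None,
    smooth_rate: bool = True,
) -> np.ndarray:
    """Advance the initiation measure omega by one increment.

    ``omega += delta_eps_pl / eps_onset(rate)``.  When omega crosses 1 the
    current flow stress (``sigma_flow``, if provided) is recorded as the
    softening reference stress.  Returns the updated omega array.
    """
    inc = np.atleast_1d(np.asarray(delta_eps_pl, dtype=float))
    if np.any(inc < 0):
        raise ValueError("plastic strain increments must be non-negative")
    rate = np.broadcast_to(np.asarray(eps_dot_pl, dtype=float), inc.shape)
    if smooth_rate:
        rate = smoothed_rate(state, rate, card.rate_smoothing)
    eps_on = onset_strain(card, rate)
    was = state.initiated.copy()
    state.omega = state.omega + inc / eps_on
    crossed = state.initiated & ~was
    if sigma_flow is not None and np.any(crossed):
        sf = np.broadcast_to(np.asarray(sigma_flow, dtype=float), inc.shape)
        state.sigma_y0_at_onset = np.where(crossed, sf, state.sigma_y0_at_onset)
    return state.omega


def evolve_damage(state: DamageState, delta_eps_pl, fracture_energy: float) -> np.ndarray:
    """Advance the softening variable d for initiated points.

    Linear displacement softening: ``u_pl += L_e * delta_eps_pl`` and
    ``d = min(1, u_pl / u_f)`` with ``u_f = 2 G / sigma_y0_at_onset``, which
    dissipates exactly G per unit fractured area over the full softening
    branch.  Non-initiated points are untouched.  Returns the updated d.
    """
    inc = np.atleast_1d(np.asarray(delta_eps_pl, dtype=float))
    act = state.initiated & (inc > 0)
    if np.any(act & (state.sigma_y0_at_onset <= 0)):
        raise DamageStateError("softening requested with no recorded onset stress")
    state.u_pl = np.where(act, state.u_pl + state.char_length * inc, state.u_pl)
    u_f = np.where(state.sigma_y0_at_onset > 0, 2.0 * fracture_energy / np.maximum(state.sigma_y0_at_onset, 1e-30), np.inf)
    d_new = np.minimum(1.0, state.u_pl / u_f)
    state.d = np.maximum(state.d, np.where(act | state.initiated, d_new, state.d))
    return state.d


def apply_damage(stress: np.ndarray, d) -> np.ndarray:
    """Degrade stresses by (1 - d); d must lie in [0, 1]."""
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0) or np.any(dd > 1):
        raise DamageStateError("damage variable outside [0, 1]")
    return np.asarray(stress, dtype=float) * (1.0 - dd)[..., None]


def update_deletion(state: DamageState, card: DamageCard) -> np.ndarray:
    """Flag points whose damage reached the deletion threshold (irreversible)."""
    state.deleted |= state.d >= card.deletion_threshold
    return state.deleted


def trabecular_failure(eps_pl, card: DamageCard):
    """Deletion decision for trabecular points: eps_pl >= cap (default 0.06)."""
    eps = np.asarray(eps_pl, dtype=float)
    out = eps >= card.trabecular_cap
    return out if out.ndim else bool(out)
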