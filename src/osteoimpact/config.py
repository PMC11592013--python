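"""YAML scenario configuration.

A scenario file holds optional blocks; anything omitted falls back to the
calibrated defaults::

    fixture: plate            # plate | arch
    speed_kmh: 20
    duration_s: 0.005
    plate: {span_mm: 40, width_mm: 40, cortical_mm: 1.5, core_mm: 7.0, element_mm: 1.5}
    arch: {radius_mm: 30, angle_deg: 100, width_mm: 10}
    contact: {c0_mm: 1.5, p0_MPa: 100.0, mu: 0.2}
    impactor: {length_mm: 200, diameter_mm: 40, mass_kg: 2}
    materials:
      cortical: {name: cortical, phase: cortical, E_GPa: 13.7, nu: 0.3, rho_g_cm3: 2.12,
                 hardening: [[0.0, 110.0], [0.02, 180.0]],
                 cowper_symonds: {D: 360.7, n: 4.61, enabled: true}}
      trabecular: {...}
    damage: {onset_table: [[0.02, 0.33, 0.0], ...], G_mJ_per_mm2: 1.54,
             trabecular_cap: 0.06, deletion_threshold: 0.99}
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .contact import ContactLaw, FrictionModel
from .damage import DamageCard
from .geometry import ArchSpec, PlateSpec
from .materials import MaterialCard, cortical_card, trabecular_card
from .scenarios import ImpactScenario

__all__ = ["scenario_from_dict", "load_scenario", "plate_spec_from_dict"]


def plate_spec_from_dict(d: dict) -> PlateSpec:
    return PlateSpec(
        span=d.get("span_mm", 40.0),
        width=d.get("width_mm", 40.0),
        cortical_thickness=d.get("cortical_mm", 1.5),
        core_thickness=d.get("core_mm", 7.0),
        element_size=d.get("element_mm", 1.5),
        curvature_radius=d.get("curvature_radius_mm", math.inf),
        support=d.get("support", "bridge"),
        jitter=d.get("jitter", 0.0),
        seed=d.get("seed", 0),
    )


def arch_spec_from_dict(d: dict) -> ArchSpec:
    return ArchSpec(
        radius=d.get("radius_mm", 30.0),
        angle_deg=d.get("angle_deg", 100.0),
        width=d.get("width_mm", 10.0),
        cortical_thickness=d.get("cortical_mm", 1.5),
        core_thickness=d.get("core_mm", 7.0),
        element_size=d.get("element_mm", 1.5),
    )


def scenario_from_dict(cfg: dict) -> ImpactScenario:
    mats = cfg.get("materials", {})
    cort = MaterialCard.from_dict(mats["cortical"]) if "cortical" in mats else cortical_card()
    trab = MaterialCard.from_dict(mats["trabecular"]) if "trabecular" in mats else trabecular_card()
    contact_cfg = cfg.get("contact", {})
    impactor_cfg = cfg.get("impactor", {})
    return ImpactScenario(
        fixture=cfg.get("fixture", "plate"),
        plate=plate_spec_from_dict(cfg.get("plate", {})),
        arch=arch_spec_from_dict(cfg.get("arch", {})),
        cortical=cort,
        trabecular=trab,
        damage=DamageCard.from_dict(cfg["damage"]) if "damage" in cfg else DamageCard(),
        contact=ContactLaw(c0=contact_cfg.get("c0_mm", 1.5), p0=contact_cfg.get("p0_MPa", 100.0)),
        friction=FrictionModel(mu=contact_cfg.get("mu", 0.2)),
        speed_kmh=cfg.get("speed_kmh", 20.0),
        impactor_mass_kg=impactor_cfg.get("mass_kg", 2.0),
        impactor_length=impactor_cfg.get("length_mm", 200.0),
        impactor_diameter=impactor_cfg.get("diameter_mm", 40.0),
        duration=cfg.get("duration_s", 0.02),
        dt_target=cfg.get("dt_target_s", 1.0e-7),
        output_interval=cfg.get("output_interval_s", 1.0e-5),
        snapshot_interval=cfg.get("snapshot_interval_s", 5.0e-4),
        mass_scaling_budget=cfg.get("mass_scaling_budget", 0.01),
    )


def load_scenario(path) -> ImpactScenario:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return scenario_from_dict(cfg)
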