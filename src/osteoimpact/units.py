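"""Unit system and interface conversions.

The package works internally in a consistent mm-N-s-tonne system:

========  ==============  =================
quantity  internal unit   typical interface
========  ==============  =================
length    mm              mm
force     N               N (kgf reported alongside)
time      s               s
mass      tonne           kg
stress    MPa (N/mm^2)    GPa at material cards
density   tonne/mm^3      g/cm^3
energy    mJ (N*mm)       mJ
speed     mm/s            km/h
========  ==============  =================

Keeping this system means every bone constant quoted in MPa, mm and
mJ/mm^2 enters the solver unscaled.
"""

GRAVITY_KGF = 9.80665  # N per kgf

GPA_TO_MPA = 1.0e3
G_PER_CM3_TO_TONNE_PER_MM3 = 1.0e-9
KG_TO_TONNE = 1.0e-3
KMH_TO_MM_S = 1.0e6 / 3600.0


def gpa_to_mpa(value: float) -> float:
    return value * GPA_TO_MPA


def mpa_to_gpa(value: float) -> float:
    return value / GPA_TO_MPA


def g_cm3_to_internal(value: float) -> float:
    """g/cm^3 -> tonne/mm^3."""
    return value * G_PER_CM3_TO_TONNE_PER_MM3


def internal_to_g_cm3(value: float) -> float:
    return value / G_PER_CM3_TO_TONNE_PER_MM3


def kg_to_tonne(value: float) -> float:
    return value * KG_TO_TONNE


def tonne_to_kg(value: float) -> float:
    return value / KG_TO_TONNE


def kmh_to_mm_s(value: float) -> float:
    return value * KMH_TO_MM_S


def newton_to_kgf(value: float) -> float:
    return value / GRAVITY_KGF
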