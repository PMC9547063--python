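"""Unit conventions and physical constants.

All geometry is in micrometres; the z axis is cortical depth (0 at the pial
surface, increasing downward).  Pressures are in mmHg, flow rates in
µm³/ms, viscosities in Pa·s.  The single conversion factor below turns a
Poiseuille resistance evaluated in (Pa·s, µm) units into mmHg·ms/µm³ so
that q [µm³/ms] = Δp [mmHg] / R [mmHg·ms/µm³].
"""

MMHG_TO_PA = 133.322387415

#: multiply 128·µ[Pa·s]·L[µm]/(π·D[µm]^4) by this to get R in mmHg·ms/µm³
RESISTANCE_UNIT = 1.0e3 / MMHG_TO_PA

#: default dynamic plasma viscosity, Pa·s (a documented default, not a
#: measured value of any particular dataset)
DEFAULT_PLASMA_VISCOSITY = 1.2e-3

#: default mouse red blood cell volume, µm³ (documented constant)
DEFAULT_RBC_VOLUME = 55.0

#: mass density of blood, kg/m³ (Reynolds-number report only)
BLOOD_DENSITY = 1050.0

VESSEL_TYPES = (
    "pial_artery",
    "descending_arteriole",
    "capillary",
    "ascending_venule",
    "pial_vein",
)

ARTERIAL_TYPES = ("pial_artery", "descending_arteriole")
VENOUS_TYPES = ("pial_vein", "ascending_venule")
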