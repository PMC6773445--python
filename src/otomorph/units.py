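"""Unit conventions and conversions.

Canonical internal units are micrometre (length), hour (time), Pascal
(pressure/stress) and picolitre (volume at I/O boundaries).  Conversions are
applied only at interfaces; all solvers work in the canonical units.
"""

#: cubic micrometres per picolitre
UM3_PER_PL = 1.0e3

#: seconds per hour
S_PER_HR = 3600.0

#: square micrometres per square metre
UM2_PER_M2 = 1.0e12


def pl_to_um3(v_pl: float) -> float:
    """Picolitres -> cubic micrometres."""
    return v_pl * UM3_PER_PL


def um3_to_pl(v_um3: float) -> float:
    """Cubic micrometres -> picolitres."""
    return v_um3 / UM3_PER_PL


def pa_s_to_pa_hr(mu_pa_s: float) -> float:
    """Viscosity, Pa*s -> Pa*hr (internal unit for the growth model)."""
    return mu_pa_s / S_PER_HR


def pa_hr_to_pa_s(mu_pa_hr: float) -> float:
    """Viscosity, Pa*hr -> Pa*s (reporting unit, matching the literature)."""
    return mu_pa_hr * S_PER_HR


def um_per_s_to_um_per_hr(v: float) -> float:
    return v * S_PER_HR


def um_per_hr_to_um_per_s(v: float) -> float:
    return v / S_PER_HR
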