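"""Internal unit system and physical constants.

Coordinates are in Angstrom, time in femtoseconds, mass in unified atomic
mass units (amu) and charge in elementary charges e.  The derived energy
unit amu*A^2/fs^2 equals exactly 1e4 kJ/mol in the molar-mass convention,
which makes force-field constants quoted in kJ/mol trivial to convert.
Wavenumbers are cm^-1 throughout the public API.
"""

import scipy.constants as _const

#: speed of light in cm/fs; converts frequency (fs^-1) to wavenumber (cm^-1)
C_CM_PER_FS: float = _const.c * 100.0 * 1e-15

#: kJ/mol per internal energy unit (amu A^2 fs^-2)
KJ_MOL_PER_INTERNAL: float = 1e4

#: Boltzmann constant in internal energy per kelvin
KB_INTERNAL: float = _const.R / 1000.0 / KJ_MOL_PER_INTERNAL  # kJ/mol/K -> internal

#: Coulomb constant e^2/(4 pi eps0) in internal energy * Angstrom
COULOMB_INTERNAL: float = (
    _const.e**2 / (4.0 * _const.pi * _const.epsilon_0) * _const.N_A / 1e3 * 1e10
) / KJ_MOL_PER_INTERNAL  # kJ/mol*A per e^2 -> internal

MASS_O: float = 15.999
MASS_H: float = 1.008


def wavenumber_to_freq(nu_cm: float) -> float:
    """cm^-1 -> cyclic frequency in fs^-1."""
    return nu_cm * C_CM_PER_FS


def freq_to_wavenumber(f_fs: float) -> float:
    """cyclic frequency in fs^-1 -> cm^-1."""
    return f_fs / C_CM_PER_FS
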