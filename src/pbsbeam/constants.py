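"""Physical constants and proton kinematics helpers.

All energies in MeV, lengths in cm, angles in rad unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

#: proton rest mass energy, MeV
PROTON_MASS_MEV = 938.272

#: electron rest mass energy, MeV
ELECTRON_MASS_MEV = 0.510999

#: Bethe prefactor K = 4 pi N_A r_e^2 m_e c^2, MeV cm^2 / mol
BETHE_K = 0.307075

#: Gaussian FWHM / sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: J per MeV
JOULE_PER_MEV = 1.602176634e-13

#: Gy per (MeV deposited per gram)
GY_PER_MEV_PER_G = 1.602176634e-10

#: radiation length of water, cm
X0_WATER_CM = 36.08

# element -> (Z, A) for the material compositions used in the HU tables
ELEMENTS = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "Al": (13, 26.982),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
}


def momentum_from_kinetic(kinetic_energy):
    """pc (MeV) of a proton with kinetic energy T: pc = sqrt(T^2 + 2 T m_p c^2)."""
    t = np.asarray(kinetic_energy, dtype=float)
    return np.sqrt(t * t + 2.0 * t * PROTON_MASS_MEV)


def kinetic_from_momentum(pc):
    """Kinetic energy (MeV) of a proton with momentum pc (MeV)."""
    pc = np.asarray(pc, dtype=float)
    return np.sqrt(pc * pc + PROTON_MASS_MEV**2) - PROTON_MASS_MEV


def beta_gamma(kinetic_energy):
    """Relativistic (beta, gamma) of a proton with kinetic energy T (MeV)."""
    t = np.asarray(kinetic_energy, dtype=float)
    gamma = 1.0 + t / PROTON_MASS_MEV
    beta = np.sqrt(1.0 - 1.0 / (gamma * gamma))
    return beta, gamma


def pv(kinetic_energy):
    """p*v in MeV: pc * beta, the quantity entering the Highland formula."""
    beta, _ = beta_gamma(kinetic_energy)
    return momentum_from_kinetic(kinetic_energy) * beta
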