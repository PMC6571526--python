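"""Monitor-unit to number-of-protons calibration.

The machine delivers protons until the nozzle chamber has collected the
planned MU, so for each nominal energy there is a fixed conversion factor
k(E) = d_TPS(E) / d_MC(E): the TPS-side integrated dose per MU divided by
the simulated integrated dose per source proton.  k is independent of the
MU of the calibration plan and is represented by a second-order polynomial
in the nominal energy; a beamlet planned with MU monitor units is then
simulated with N_p = k(E) * MU source protons (a real-valued weight).

Integral (not point) dose is the calibration observable: with a phantom
and scoring volume large enough to capture essentially all deposited
energy, the integral is insensitive to how lateral scattering spreads the
dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import DoseGrid


@dataclass(frozen=True)
class MUCalibrationRecord:
    """One calibration beam: single beamlet, one energy, one MU value."""

    energy_nominal: float    # MeV
    mu: float                # MU
    d_tps_per_mu: float      # Gy*cm^3 per MU (TPS-side integral dose)
    d_mc_per_proton: float   # Gy*cm^3 per source proton (simulated)

    def __post_init__(self):
        if min(self.energy_nominal, self.mu,
               self.d_tps_per_mu, self.d_mc_per_proton) <= 0:
            raise ValueError("all record fields must be positive")


@dataclass
class MUCalibration:
    """Second-order polynomial k(E): protons per MU vs nominal energy."""

    coeffs_k: np.ndarray
    fit_range: tuple[float, float]

    def k(self, energy_nominal):
        e = np.asarray(energy_nominal, dtype=float)
        lo, hi = self.fit_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(f"energy outside calibration range [{lo}, {hi}]")
        return np.polyval(self.coeffs_k, e)


def integrated_dose(grid: DoseGrid) -> float:
    """Total integral dose (Gy*cm^3): sum of voxel dose x voxel volume."""
    return float(grid.dose.sum() * grid.voxel_volume)


def compute_k(d_tps_per_mu: float, d_mc_per_proton: float) -> float:
    """k = d_TPS / d_MC, the protons-per-MU factor for one nominal energy."""
    if d_mc_per_proton <= 0:
        raise ValueError("d_mc_per_proton must be positive")
    return d_tps_per_mu / d_mc_per_proton


def fit_k_polynomial(records: list[MUCalibrationRecord]) -> MUCalibration:
    """Order-2 least-squares fit of k over the calibration energies."""
    energies = np.array([r.energy_nominal for r in records], dtype=float)
    if len(np.unique(energies)) < 3:
        raise ValueError("need >= 3 distinct calibration energies")
    ks = np.array([compute_k(r.d_tps_per_mu, r.d_mc_per_proton)
                   for r in records])
    coeffs = np.polyfit(energies, ks, 2)
    lo, hi = float(energies.min()), float(energies.max())
    dense = np.linspace(lo, hi, 512)
    if np.any(np.polyval(coeffs, dense) <= 0):
        raise ValueError("fitted k(E) is non-positive inside the fit range")
    return MUCalibration(coeffs_k=coeffs, fit_range=(lo, hi))


def protons_for_beamlet(calibration: MUCalibration, energy_nominal: float,
                        mu: float) -> float:
    """N_p = k(E) * MU, as a real-valued source weight (not rounded)."""
    if mu < 0:
        raise ValueError("MU must be non-negative")
    return float(calibration.k(energy_nominal)) * mu


def read_mu_records_csv(path) -> list[MUCalibrationRecord]:
    """CSV columns: energy_MeV, mu, d_tps_integral, d_mc_integral_per_proton."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["energy_MeV", "mu", "d_tps_integral", "d_mc_integral_per_proton"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"MU record CSV missing columns: {missing}")
    return [MUCalibrationRecord(r.energy_MeV, r.mu,
                                r.d_tps_integral / r.mu,
                                r.d_mc_integral_per_proton)
            for r in df.itertuples()]
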