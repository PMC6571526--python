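"""Energy and momentum-spread calibration against measured Bragg curves.

The source spectrum is a Gaussian in energy whose mean fixes the Bragg
peak position and whose spread (expressed as a fractional momentum FWHM)
controls the peak-to-plateau ratio.  Calibration inverts measured
depth-dose curves in water by exhaustive, sequential grid search — the
mean energy first (peak position), the spread second (peak/plateau) — and
then characterizes nominal energy -> (E_MC, momentum FWHM) with
polynomials so no lookup tables are needed at run time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import FWHM_PER_SIGMA, PROTON_MASS_MEV, momentum_from_kinetic
from .transport import DepthDoseCurve, depth_dose


@dataclass
class EnergyCalibration:
    """Polynomials mapping nominal energy to simulation energy and spread."""

    coeffs_energy: np.ndarray
    coeffs_momentum_fwhm: np.ndarray
    fit_range: tuple[float, float]

    def _check(self, energy):
        e = np.asarray(energy, dtype=float)
        lo, hi = self.fit_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(f"energy outside calibration range [{lo}, {hi}]")
        return e

    def energy_mc(self, energy_nominal):
        return np.polyval(self.coeffs_energy, self._check(energy_nominal))

    def momentum_fwhm(self, energy_nominal):
        v = np.polyval(self.coeffs_momentum_fwhm, self._check(energy_nominal))
        return np.clip(v, 0.0, None)


def peak_metrics(curve: DepthDoseCurve,
                 plateau_depth_fraction: float = 0.25) -> tuple[float, float]:
    """(peak depth, peak/plateau ratio) of a Bragg curve.

    Peak depth by parabolic interpolation around the discrete maximum;
    plateau dose = mean dose over [0, fraction x peak depth].
    """
    d, y = curve.depths, curve.dose
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise ValueError("no interior maximum: curve has no Bragg peak")
    if np.allclose(y, y[0]):
        raise ValueError("flat curve has no Bragg peak")
    # parabola through the three points around the maximum
    x0, x1, x2 = d[i - 1], d[i], d[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate (plateau-like); fall back to the grid maximum
        peak_depth = float(x1)
        peak_dose = float(y1)
    else:
        peak_depth = float(-b / (2 * a))
        c = y1 - a * x1**2 - b * x1
        peak_dose = float(a * peak_depth**2 + b * peak_depth + c)
    plateau_mask = d <= plateau_depth_fraction * peak_depth
    if not plateau_mask.any():
        raise ValueError("no samples in the plateau region")
    plateau = float(y[plateau_mask].mean())
    if plateau <= 0:
        raise ValueError("plateau dose is zero")
    return peak_depth, peak_dose / plateau


def r80_distal(curve: DepthDoseCurve) -> float:
    """Distal depth at 80% of peak dose (optional range metric)."""
    d, y = curve.depths, curve.dose
    i = int(np.argmax(y))
    yy = y[i:] / y.max()
    dd = d[i:]
    return float(np.interp(0.8, yy[::-1], dd[::-1]))


def _grid_fit_1d(target: float, values: np.ndarray, metric) -> tuple[float, bool]:
    """Pick the grid value minimizing |metric(v) - target|; flag boundary."""
    errs = np.array([abs(metric(v) - target) for v in values])
    i = int(np.argmin(errs))
    return float(values[i]), i in (0, len(values) - 1)


def fit_energy_and_spread(measured: DepthDoseCurve,
                          energy_grid: np.ndarray,
                          spread_grid: np.ndarray,
                          forward=None,
                          plateau_depth_fraction: float = 0.25,
                          refine: bool = True) -> tuple[float, float]:
    """Sequential exhaustive fit of (E_MC, momentum FWHM) to a Bragg curve.

    Stage 1 scans ``energy_grid`` for the peak position (evaluated at the
    mid spread, where the peak depth is nearly spread-independent); stage 2
    scans ``spread_grid`` for the peak/plateau ratio at the fixed energy.
    One refinement pass halves each grid step about the incumbent, and the
    two stages are run a second time so the small residual coupling between
    peak position and peak/plateau ratio cannot bias the spread.
    """
    if forward is None:
        forward = lambda e, s: depth_dose(e, s, depths=measured.depths)
    energy_grid = np.asarray(energy_grid, dtype=float)
    spread_grid = np.asarray(spread_grid, dtype=float)
    pk_meas, ratio_meas = peak_metrics(measured, plateau_depth_fraction)
    s_best = float(spread_grid[len(spread_grid) // 2])
    e_best = None

    def peak_of(e):
        return peak_metrics(forward(e, s_best), plateau_depth_fraction)[0]

    def ratio_of(s):
        return peak_metrics(forward(e_best, s), plateau_depth_fraction)[1]

    n_passes = 2 if refine else 1
    for sweep in range(n_passes):
        e_best, e_edge = _grid_fit_1d(pk_meas, energy_grid, peak_of)
        if e_edge and sweep == 0:
            warnings.warn("energy grid does not bracket the optimum",
                          stacklevel=2)
        s_best, s_edge = _grid_fit_1d(ratio_meas, spread_grid, ratio_of)
        if s_edge and sweep == 0:
            warnings.warn("spread grid does not bracket the optimum",
                          stacklevel=2)
        if refine:
            de = np.diff(energy_grid).mean()
            ds = np.diff(spread_grid).mean()
            for _ in range(2):  # successive halvings about the incumbent
                de /= 2.0
                fine_e = np.array([e_best - de, e_best, e_best + de])
                e_best, _ = _grid_fit_1d(pk_meas, fine_e, peak_of)
            for _ in range(2):
                ds /= 2.0
                fine_s = np.clip(np.array([s_best - ds, s_best, s_best + ds]),
                                 0.0, None)
                s_best, _ = _grid_fit_1d(ratio_meas, fine_s, ratio_of)
    return e_best, s_best


def fit_energy_polynomials(pairs, order_energy: int = 3,
                           order_fwhm: int = 3) -> EnergyCalibration:
    """Fit E_MC(E_nom) and momentum-FWHM(E_nom) polynomials.

    ``pairs`` is a list of (E_nom, E_MC, fwhm) tuples.  The fitted E_MC
    polynomial must be monotone increasing over the fit range (checked on
    a dense grid); otherwise a lower order is advised.
    """
    pairs = list(pairs)
    e_nom = np.array([p[0] for p in pairs], dtype=float)
    e_mc = np.array([p[1] for p in pairs], dtype=float)
    fwhm = np.array([p[2] for p in pairs], dtype=float)
    n_distinct = len(np.unique(e_nom))
    if n_distinct < max(order_energy, order_fwhm) + 1:
        raise ValueError(f"need >= {max(order_energy, order_fwhm) + 1} distinct "
                         f"nominal energies, got {n_distinct}")
    ce = np.polyfit(e_nom, e_mc, order_energy)
    cf = np.polyfit(e_nom, fwhm, order_fwhm)
    lo, hi = float(e_nom.min()), float(e_nom.max())
    dense = np.linspace(lo, hi, 512)
    if np.any(np.diff(np.polyval(ce, dense)) <= 0):
        raise ValueError("fitted E_MC(E_nom) is not monotone increasing; "
                         "try a lower polynomial order")
    return EnergyCalibration(coeffs_energy=ce, coeffs_momentum_fwhm=cf,
                             fit_range=(lo, hi))


def momentum_energy_conversions(value: float, direction: str,
                                kinetic_energy: float) -> float:
    """Convert between fractional energy sigma and fractional momentum FWHM.

    FWHM = 2 sqrt(2 ln 2) sigma; the energy<->momentum Jacobian dT/dp is
    evaluated numerically from the relativistic relation
    pc = sqrt(T^2 + 2 T m_p c^2).
    """
    if kinetic_energy <= 0:
        raise ValueError("kinetic energy must be positive")
    if value < 0:
        raise ValueError("spread must be non-negative")
    t = float(kinetic_energy)
    pc = float(momentum_from_kinetic(t))
    h = t * 1e-6
    dp_dt = (momentum_from_kinetic(t + h) - momentum_from_kinetic(t - h)) / (2 * h)
    if direction == "sigmaE->fwhmP":
        sigma_t = value * t                  # fractional -> absolute MeV
        sigma_pc = sigma_t * dp_dt
        return float(FWHM_PER_SIGMA * sigma_pc / pc)
    elif direction == "fwhmP->sigmaE":
        sigma_pc = value * pc / FWHM_PER_SIGMA
        sigma_t = sigma_pc / dp_dt
        return float(sigma_t / t)
    raise ValueError(f"unknown direction {direction!r}")
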