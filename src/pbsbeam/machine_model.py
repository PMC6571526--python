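"""Dual-virtual-source beam geometry and energy-dependent optics.

A scanned cyclotron beam is focused by two scanning magnets sitting at
different planes, so the beam appears to diverge from two distinct virtual
sources, one per axis (VSAD_x and VSAD_y, both upstream of the isocenter).
The simulation source is fixed at the focal point closest to the isocenter
(here the x focus): there the beam is a *line* source — zero width in x,
already spread in y — with energy-dependent divergences applied per axis.

Coordinate frame: right-handed, beam travels along +z, isocenter at the
origin, sources at negative z.  Lengths in cm, angles in rad, energies in
MeV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

FORMAT_TAG = "pbsmachine/1"


@dataclass(frozen=True)
class SpotMeasurement:
    """In-air spot size at one plane: Gaussian sigmas in x and y."""

    energy_nominal: float  # MeV
    z: float               # cm, isocenter = 0, source side negative
    sigma_x: float         # cm
    sigma_y: float         # cm

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("spot sigmas must be positive")


@dataclass
class OpticsModel:
    """Polynomial spot-size and divergence vs energy at the MC origin plane.

    sigma_x(E) is identically zero at the origin plane by construction
    (line source); only its divergence carries the x spread.
    """

    coeffs_sigma_x: np.ndarray
    coeffs_sigma_y: np.ndarray
    coeffs_div_x: np.ndarray
    coeffs_div_y: np.ndarray
    energy_range: tuple[float, float]

    def _eval(self, coeffs, energy):
        lo, hi = self.energy_range
        e = np.asarray(energy, dtype=float)
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(f"energy outside optics range [{lo}, {hi}] MeV")
        return np.polyval(coeffs, e)

    def sigma_x(self, energy):
        return self._eval(self.coeffs_sigma_x, energy)

    def sigma_y(self, energy):
        return self._eval(self.coeffs_sigma_y, energy)

    def div_x(self, energy):
        return self._eval(self.coeffs_div_x, energy)

    def div_y(self, energy):
        return self._eval(self.coeffs_div_y, energy)


@dataclass
class BeamletSource:
    """Phase-space description of one spot at the simulation origin plane."""

    origin_z: float
    center_x: float
    center_y: float
    sigma_x: float
    sigma_y: float
    div_x: float
    div_y: float
    direction: np.ndarray
    mean_energy_mc: float
    momentum_fwhm_fraction: float
    weight_protons: float = 0.0

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        if self.mean_energy_mc <= 0:
            raise ValueError("mean energy must be positive")
        if self.momentum_fwhm_fraction < 0:
            raise ValueError("momentum spread must be non-negative")


@dataclass
class MachineModel:
    """Fitted beam-line description: geometry, optics and calibrations."""

    z_vsad_x: float
    z_vsad_y: float
    optics: OpticsModel
    energy_calibration: "object" = None   # EnergyCalibration, set after fitting
    mu_calibration: "object" = None       # MUCalibration, set after fitting
    energy_limits: tuple[float, float] = (98.0, 230.0)
    snout_z: float = -50.0
    steering: str = "single_origin"       # or "two_plane"

    def __post_init__(self):
        if self.z_vsad_x >= 0 or self.z_vsad_y >= 0:
            raise ValueError("virtual sources must be upstream of the isocenter")

    @property
    def origin_z(self) -> float:
        """MC origin plane: the focal point closest to the isocenter."""
        return max(self.z_vsad_x, self.z_vsad_y)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def fit_virtual_source(measurements: list[SpotMeasurement], axis: str) -> float:
    """Locate the virtual source: z where the spot size extrapolates to zero.

    All energies are pooled with a shared intercept (the focal point is a
    property of the magnets, not the energy): sigma_e(z) = s_e (z - z0),
    solved by profiled least squares over z0.  With a single energy this
    reduces to the ordinary straight-line z-intercept.
    """
    if axis not in ("X", "Y"):
        raise ValueError("axis must be 'X' or 'Y'")
    getter = (lambda m: m.sigma_x) if axis == "X" else (lambda m: m.sigma_y)
    by_e: dict[float, list[SpotMeasurement]] = {}
    for m in measurements:
        by_e.setdefault(m.energy_nominal, []).append(m)
    zs_all = np.array([m.z for m in measurements])
    if len(np.unique(zs_all)) < 2:
        raise ValueError("need measurements at >= 2 distinct planes")

    groups = []
    for e, ms in by_e.items():
        z = np.array([m.z for m in ms])
        s = np.array([getter(m) for m in ms])
        if len(np.unique(z)) < 2:
            raise ValueError(f"energy {e} MeV has fewer than 2 distinct planes")
        groups.append((z, s))

    def slope_and_sse(z0):
        sse = 0.0
        slopes = []
        for z, s in groups:
            dz = z - z0
            slope = float(np.dot(s, dz) / np.dot(dz, dz))
            slopes.append(slope)
            sse += float(np.sum((s - slope * dz) ** 2))
        return slopes, sse

    if len(groups) == 1:
        z, s = groups[0]
        a, b = np.polyfit(z, s, 1)
        if a <= 0:
            raise ValueError("non-positive sigma(z) slope: beam converging "
                             "over the measurement span, data inconsistent")
        z0 = float(-b / a)
    else:
        zmin = float(zs_all.min())
        res = minimize_scalar(lambda z0: slope_and_sse(z0)[1],
                              bounds=(zmin - 2000.0, zmin - 1e-6),
                              method="bounded",
                              options={"xatol": 1e-10})
        z0 = float(res.x)
        slopes, _ = slope_and_sse(z0)
        if min(slopes) <= 0:
            raise ValueError("non-positive sigma(z) slope for at least one "
                             "energy: inconsistent data")
    if z0 >= zs_all.min():
        raise ValueError("fitted virtual source is not upstream of all "
                         "measurement planes")
    return z0


def _backproject(z: np.ndarray, sigma: np.ndarray, z_origin: float,
                 force_sigma0_zero: bool = False) -> tuple[float, float]:
    """Least squares of sigma^2 = sigma0^2 + div^2 (z - z_origin)^2."""
    u = (z - z_origin) ** 2
    s2 = sigma**2
    if force_sigma0_zero:
        div2 = float(np.dot(s2, u) / np.dot(u, u))
        s02 = 0.0
    else:
        a = np.vstack([np.ones_like(u), u]).T
        (s02, div2), *_ = np.linalg.lstsq(a, s2, rcond=None)
    if s02 < 0:
        warnings.warn("negative fitted sigma0^2 clamped to 0", stacklevel=2)
        s02 = 0.0
    div2 = max(div2, 0.0)
    return float(np.sqrt(s02)), float(np.sqrt(div2))


def fit_optics(measurements: list[SpotMeasurement], z_origin: float,
               order: int = 3) -> OpticsModel:
    """Back-project spot sizes to the origin plane and fit polynomials in E.

    Per energy, sigma^2(z) = sigma0^2 + div^2 (z - z_origin)^2 is solved in
    closed form (sigma0_x forced to 0: line source).  The per-energy
    (sigma0, div) values are then fitted with polynomials of ``order`` in
    the nominal energy.
    """
    by_e: dict[float, list[SpotMeasurement]] = {}
    for m in measurements:
        by_e.setdefault(m.energy_nominal, []).append(m)
    energies = sorted(by_e)
    if order >= len(energies) and len(energies) > 1:
        raise ValueError(f"polynomial order {order} needs more than "
                         f"{len(energies)} energies")
    s0y, divx, divy = [], [], []
    for e in energies:
        ms = by_e[e]
        z = np.array([m.z for m in ms])
        if len(np.unique(z)) < 3:
            raise ValueError(f"energy {e} MeV has fewer than 3 planes")
        if z_origin >= z.min():
            raise ValueError("origin must be upstream of all planes")
        sx = np.array([m.sigma_x for m in ms])
        sy = np.array([m.sigma_y for m in ms])
        _, dx = _backproject(z, sx, z_origin, force_sigma0_zero=True)
        sy0, dy = _backproject(z, sy, z_origin)
        s0y.append(sy0)
        divx.append(dx)
        divy.append(dy)
    e_arr = np.array(energies, dtype=float)
    if len(energies) == 1:
        fit = lambda v: np.array([v[0]])  # constant polynomial
    else:
        fit = lambda v: np.polyfit(e_arr, np.array(v), min(order, len(energies) - 1))
    return OpticsModel(
        coeffs_sigma_x=np.array([0.0]),
        coeffs_sigma_y=fit(s0y),
        coeffs_div_x=fit(divx),
        coeffs_div_y=fit(divy),
        energy_range=(float(e_arr.min()), float(e_arr.max())),
    )


# --------------------------------------------------------------------------
# Beamlet construction and prediction
# --------------------------------------------------------------------------

def beamlet_origin_state(machine: MachineModel, energy_nominal: float,
                         x_iso: float, y_iso: float,
                         weight_protons: float = 0.0) -> BeamletSource:
    """Source state of one spot at the MC origin plane.

    The direction is the unit vector from the origin plane position on the
    beam axis to the spot position at the isocenter ("single_origin"
    steering); "two_plane" steering instead anchors the y deflection at the
    upstream y focus, which offsets the beamlet center in y at the origin
    plane.
    """
    lo, hi = machine.energy_limits
    if not (lo <= energy_nominal <= hi):
        side = "lower" if energy_nominal < lo else "upper"
        raise ValueError(f"energy {energy_nominal} MeV violates the {side} "
                         f"machine limit ({lo}-{hi} MeV)")
    z0 = machine.origin_z
    cx, cy = 0.0, 0.0
    if machine.steering == "two_plane":
        # y deflection originates at the y focus; at the origin plane the
        # beamlet center is already displaced in y
        fy = min(machine.z_vsad_x, machine.z_vsad_y)
        cy = y_iso * (z0 - fy) / (0.0 - fy)
        vec = np.array([x_iso - cx, y_iso - cy, -z0])
    else:
        vec = np.array([x_iso, y_iso, -z0])
    direction = vec / np.linalg.norm(vec)
    ecal = machine.energy_calibration
    if ecal is not None:
        e_mc = float(ecal.energy_mc(energy_nominal))
        fwhm = float(ecal.momentum_fwhm(energy_nominal))
    else:
        e_mc, fwhm = float(energy_nominal), 0.0
    return BeamletSource(
        origin_z=z0, center_x=cx, center_y=cy,
        sigma_x=0.0,
        sigma_y=float(machine.optics.sigma_y(energy_nominal)),
        div_x=float(machine.optics.div_x(energy_nominal)),
        div_y=float(machine.optics.div_y(energy_nominal)),
        direction=direction,
        mean_energy_mc=e_mc, momentum_fwhm_fraction=fwhm,
        weight_protons=weight_protons,
    )


def spot_sigma_at_z(source: BeamletSource, z) -> tuple[np.ndarray, np.ndarray]:
    """In-air spot sigma at plane z: pure divergence drift, no scattering."""
    z = np.asarray(z, dtype=float)
    if np.any(z < source.origin_z):
        raise ValueError("z upstream of the source origin plane")
    d = z - source.origin_z
    sx = np.sqrt(source.sigma_x**2 + (source.div_x * d) ** 2)
    sy = np.sqrt(source.sigma_y**2 + (source.div_y * d) ** 2)
    return sx, sy


def sample_phase_space(source: BeamletSource, n: int, seed=None):
    """Draw n particles: positions, direction angles and kinetic energies.

    Positions are Gaussian about the beamlet center with (sigma_x, sigma_y);
    angular deflections Gaussian with (div_x, div_y) added to the central
    direction; energies Gaussian with the sigma implied by the momentum
    FWHM.  Returns a structured dict of arrays; reproducible under a seed.
    """
    from .constants import FWHM_PER_SIGMA
    from .transport import sigma_energy_from_momentum_fwhm

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = source.center_x + rng.standard_normal(n) * source.sigma_x
    y = source.center_y + rng.standard_normal(n) * source.sigma_y
    tx = source.direction[0] / source.direction[2] + rng.standard_normal(n) * source.div_x
    ty = source.direction[1] / source.direction[2] + rng.standard_normal(n) * source.div_y
    if source.momentum_fwhm_fraction > 0:
        sig_e = sigma_energy_from_momentum_fwhm(
            source.momentum_fwhm_fraction, source.mean_energy_mc)
        e = source.mean_energy_mc + rng.standard_normal(n) * sig_e
    else:
        e = np.full(n, source.mean_energy_mc)
    norm = np.sqrt(1.0 + tx**2 + ty**2)
    dirs = np.stack([tx / norm, ty / norm, 1.0 / norm], axis=1)
    return {"x": x, "y": y, "direction": dirs, "energy": e}


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_machine(machine: MachineModel, path) -> None:
    """Serialize a MachineModel to a human-readable JSON config."""
    def arr(a):
        return [float(v) for v in np.atleast_1d(a)]

    d = {
        "format": FORMAT_TAG,
        "z_vsad_x": machine.z_vsad_x,
        "z_vsad_y": machine.z_vsad_y,
        "snout_z": machine.snout_z,
        "energy_limits": list(machine.energy_limits),
        "steering": machine.steering,
        "optics": {
            "coeffs_sigma_x": arr(machine.optics.coeffs_sigma_x),
            "coeffs_sigma_y": arr(machine.optics.coeffs_sigma_y),
            "coeffs_div_x": arr(machine.optics.coeffs_div_x),
            "coeffs_div_y": arr(machine.optics.coeffs_div_y),
            "energy_range": list(machine.optics.energy_range),
        },
    }
    if machine.energy_calibration is not None:
        ec = machine.energy_calibration
        d["energy_calibration"] = {
            "coeffs_energy": arr(ec.coeffs_energy),
            "coeffs_momentum_fwhm": arr(ec.coeffs_momentum_fwhm),
            "fit_range": list(ec.fit_range),
        }
    if machine.mu_calibration is not None:
        mc = machine.mu_calibration
        d["mu_calibration"] = {
            "coeffs_k": arr(mc.coeffs_k),
            "fit_range": list(mc.fit_range),
        }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def load_machine(path) -> MachineModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != FORMAT_TAG:
        raise ValueError(f"unrecognized machine file format: {d.get('format')}")
    optics = OpticsModel(
        coeffs_sigma_x=np.array(d["optics"]["coeffs_sigma_x"]),
        coeffs_sigma_y=np.array(d["optics"]["coeffs_sigma_y"]),
        coeffs_div_x=np.array(d["optics"]["coeffs_div_x"]),
        coeffs_div_y=np.array(d["optics"]["coeffs_div_y"]),
        energy_range=tuple(d["optics"]["energy_range"]),
    )
    machine = MachineModel(
        z_vsad_x=d["z_vsad_x"], z_vsad_y=d["z_vsad_y"], optics=optics,
        energy_limits=tuple(d["energy_limits"]), snout_z=d["snout_z"],
        steering=d.get("steering", "single_origin"),
    )
    if "energy_calibration" in d:
        from .energy_model import EnergyCalibration

        ec = d["energy_calibration"]
        machine.energy_calibration = EnergyCalibration(
            coeffs_energy=np.array(ec["coeffs_energy"]),
            coeffs_momentum_fwhm=np.array(ec["coeffs_momentum_fwhm"]),
            fit_range=tuple(ec["fit_range"]),
        )
    if "mu_calibration" in d:
        from .mu_model import MUCalibration

        mc = d["mu_calibration"]
        machine.mu_calibration = MUCalibration(
            coeffs_k=np.array(mc["coeffs_k"]), fit_range=tuple(mc["fit_range"]))
    return machine


# --------------------------------------------------------------------------
# Commissioning CSV
# --------------------------------------------------------------------------

def read_spot_csv(path) -> list[SpotMeasurement]:
    """Read commissioning spots: energy_MeV, z_cm, sigma_x_cm, sigma_y_cm."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    required = ["energy_MeV", "z_cm", "sigma_x_cm", "sigma_y_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot CSV missing columns: {missing}")
    return [SpotMeasurement(r.energy_MeV, r.z_cm, r.sigma_x_cm, r.sigma_y_cm)
            for r in df.itertuples()]


def write_spot_csv(measurements: list[SpotMeasurement], path) -> None:
    import pandas as pd

    pd.DataFrame({
        "energy_MeV": [m.energy_nominal for m in measurements],
        "z_cm": [m.z for m in measurements],
        "sigma_x_cm": [m.sigma_x for m in measurements],
        "sigma_y_cm": [m.sigma_y for m in measurements],
    }).to_csv(path, index=False, float_format="%.17g")
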