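"""Synthetic commissioning data, plans and phantoms with known ground truth.

The bundled machine preset mimics a cyclotron PBS line of the Provision
type: virtual sources at z = -193.5 cm (x) and -231.5 cm (y), snout at
-50 cm, deliverable energies 98-230 MeV.  The VSAD positions and energy
limits are the published machine constants; every curve (divergence,
energy calibration, momentum spread, protons-per-MU) is a synthetic
ground truth of realistic magnitude, *not* read off any published figure.

Spot model: each axis's in-air sigma grows linearly from its own focal
point, sigma_a(z, E) = div_a(E) * (z - z_vsad_a), so the spot size is
exactly zero at the axis's virtual source.  div_x/div_y are chosen in the
ratio of the VSAD distances, which makes the spot circular at the
isocenter (and slightly elliptical before and after), with div_x > div_y
and sigma_y > sigma_x = 0 at the MC origin plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GY_PER_MEV_PER_G
from .machine_model import (
    BeamletSource,
    MachineModel,
    OpticsModel,
    SpotMeasurement,
    beamlet_origin_state,
)
from .mu_model import MUCalibrationRecord
from .plan_io import BeamletSpec, PlanField, PlanSummary
from .transport import (
    DepthDoseCurve,
    Phantom,
    _idd_water,
    depth_dose,
    energy_at_residual_range,
    water_range,
)


@dataclass
class MachinePreset:
    """Ground-truth machine description used by every generator."""

    z_vsad_x: float = -193.5
    z_vsad_y: float = -231.5
    snout_z: float = -50.0
    energy_limits: tuple[float, float] = (98.0, 230.0)
    # div_y(E) = a + b*E (rad); div_x scaled by the VSAD ratio
    div_y_coeffs: tuple[float, float] = (4.384e-3, -8.0e-6)
    # E_MC(E_nom) = c0 + c1*E + c2*E^2
    energy_mc_coeffs: tuple[float, float, float] = (3.0, 0.98, 2.0e-5)
    # momentum FWHM fraction vs E_nom
    fwhm_coeffs: tuple[float, float] = (1.25e-2, -3.5e-5)
    # k(E) = protons per MU, order 2
    k_coeffs: tuple[float, float, float] = (1.5e8, 5.0e5, 1.2e3)

    def div_y(self, energy):
        a, b = self.div_y_coeffs
        return a + b * np.asarray(energy, dtype=float)

    def div_x(self, energy):
        return self.div_y(energy) * (self.z_vsad_y / self.z_vsad_x)

    def sigma_x(self, energy, z):
        return self.div_x(energy) * (np.asarray(z) - self.z_vsad_x)

    def sigma_y(self, energy, z):
        return self.div_y(energy) * (np.asarray(z) - self.z_vsad_y)

    def energy_mc(self, energy_nominal):
        c0, c1, c2 = self.energy_mc_coeffs
        e = np.asarray(energy_nominal, dtype=float)
        return c0 + c1 * e + c2 * e * e

    def momentum_fwhm(self, energy_nominal):
        a, b = self.fwhm_coeffs
        return a + b * np.asarray(energy_nominal, dtype=float)

    def k(self, energy_nominal):
        c0, c1, c2 = self.k_coeffs
        e = np.asarray(energy_nominal, dtype=float)
        return c0 + c1 * e + c2 * e * e

    def machine_model(self) -> MachineModel:
        """Commissioned MachineModel for this preset.

        The geometry and optics are obtained by running the actual
        commissioning procedure (virtual-source extrapolation and
        sigma^2 back-projection) on noise-free synthetic spot data: the
        uncorrelated position/angle source drifts in quadrature while a
        point-focus beam grows linearly, so the *effective* (sigma0, div)
        that best reproduce the measured spot sizes over the in-air span
        are the fitted ones, not the naive focal-drift parameters.  The
        energy and MU calibrations are attached exactly.
        """
        from .energy_model import EnergyCalibration
        from .machine_model import fit_optics, fit_virtual_source
        from .mu_model import MUCalibration

        if getattr(self, "_machine_cache", None) is not None:
            return self._machine_cache

        lo, hi = self.energy_limits
        energies = np.linspace(lo, hi, 12)
        spots = gen_spot_measurements(self, energies)
        zx = fit_virtual_source(spots, "X")
        zy = fit_virtual_source(spots, "Y")
        optics = fit_optics(spots, max(zx, zy), order=3)
        c0, c1, c2 = self.energy_mc_coeffs
        fa, fb = self.fwhm_coeffs
        ecal = EnergyCalibration(
            coeffs_energy=np.array([c2, c1, c0]),
            coeffs_momentum_fwhm=np.array([fb, fa]),
            fit_range=(lo, hi),
        )
        k0, k1, k2 = self.k_coeffs
        mucal = MUCalibration(coeffs_k=np.array([k2, k1, k0]),
                              fit_range=(lo, hi))
        machine = MachineModel(
            z_vsad_x=zx, z_vsad_y=zy, optics=optics,
            energy_calibration=ecal, mu_calibration=mucal,
            energy_limits=self.energy_limits, snout_z=self.snout_z,
        )
        object.__setattr__(self, "_machine_cache", machine)
        return machine


PROVISION = MachinePreset()


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def gen_spot_measurements(preset: MachinePreset, energies,
                          z_planes=(-20.0, -10.0, 0.0, 10.0, 20.0),
                          noise_sd: float = 0.0,
                          seed=None) -> list[SpotMeasurement]:
    """In-air spot sizes at several planes, from the two-focal drift model."""
    z_planes = np.asarray(z_planes, dtype=float)
    if np.any(z_planes < preset.snout_z) or np.any(z_planes > 20.0):
        raise ValueError("z planes outside the instrumented in-air span")
    rng = np.random.default_rng(seed)
    out = []
    for e in np.atleast_1d(energies):
        for z in z_planes:
            sx = float(preset.sigma_x(e, z))
            sy = float(preset.sigma_y(e, z))
            if noise_sd > 0:
                sx = max(sx + rng.normal(0.0, noise_sd), 1e-4)
                sy = max(sy + rng.normal(0.0, noise_sd), 1e-4)
            out.append(SpotMeasurement(float(e), float(z), sx, sy))
    return out


def gen_depth_dose_set(preset: MachinePreset, energies,
                       noise_sd: float = 0.0, seed=None,
                       dz: float = 0.1) -> dict[float, DepthDoseCurve]:
    """Forward-engine Bragg curves at the preset's ground-truth (E_MC, spread)."""
    rng = np.random.default_rng(seed)
    out = {}
    for e in np.atleast_1d(energies):
        e_mc = float(preset.energy_mc(e))
        fwhm = float(preset.momentum_fwhm(e))
        r0 = float(water_range(e_mc))
        depths = np.arange(0.0, r0 + 3.0, dz)
        curve = depth_dose(e_mc, fwhm, depths=depths, normalize=True)
        dose = curve.dose
        if noise_sd > 0:
            dose = np.clip(dose + rng.normal(0.0, noise_sd, dose.shape), 0, None)
        out[float(e)] = DepthDoseCurve(depths, dose)
    return out


def _integral_dose_per_proton(e_mc: float, fwhm: float) -> float:
    """Analytic water integral dose per proton, Gy*cm^3 (1D engine integral)."""
    z, idd = _idd_water(e_mc, fwhm, zmax=float(water_range(e_mc)) + 3.0)
    e_dep = float(np.trapezoid(idd, z))  # MeV
    return e_dep * GY_PER_MEV_PER_G  # water density 1 g/cm^3


def gen_mu_records(preset: MachinePreset, energies,
                   mu: float = 100.0) -> list[MUCalibrationRecord]:
    """Single-beamlet calibration records, one energy per plan.

    The TPS-side integral dose per MU is k_true(E) times the engine's
    per-proton water integral, so a correct pipeline recovers k_true.
    """
    out = []
    for e in np.atleast_1d(energies):
        e_mc = float(preset.energy_mc(e))
        fwhm = float(preset.momentum_fwhm(e))
        d_mc = _integral_dose_per_proton(e_mc, fwhm)
        d_tps = float(preset.k(e)) * d_mc
        out.append(MUCalibrationRecord(float(e), mu, d_tps, d_mc))
    return out


def gen_phantom(kind: str = "water_box",
                dims: tuple[float, float, float] = (20.0, 20.0, 30.0),
                voxel: tuple[float, float, float] = (0.2, 0.2, 0.2),
                entry_z: float = -15.0) -> Phantom:
    """Voxel phantoms: uniform water, layered slabs, or a metal insert."""
    shape = tuple(int(round(d / v)) for d, v in zip(dims, voxel))
    hu = np.zeros(shape)
    if kind == "water_box":
        pass
    elif kind == "layered":
        # water / adipose / trabecular bone / water along z
        nz = shape[2]
        hu[:, :, nz // 4: nz // 2] = -98.0
        hu[:, :, nz // 2: 3 * nz // 4] = 300.0
    elif kind == "metal_insert":
        cx, cy, cz = (s // 2 for s in shape)
        w = max(1, int(round(1.0 / voxel[0])))
        hu[cx - w // 2: cx + w // 2 + 1,
           cy - w // 2: cy + w // 2 + 1,
           cz - w // 2: cz + w // 2 + 1] = 2700.0
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    origin = (-dims[0] / 2.0, -dims[1] / 2.0, entry_z)
    return Phantom(hu=hu, voxel_size=voxel, origin=origin)


def _energy_for_depth(preset: MachinePreset, depth_cm: float,
                      entry_z: float = -15.0) -> float:
    """Nominal energy whose Bragg peak sits at the given water depth."""
    from scipy.optimize import brentq

    lo, hi = preset.energy_limits

    def f(e_nom):
        return float(water_range(preset.energy_mc(e_nom))) - depth_cm

    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"depth {depth_cm} cm outside deliverable range")
    return float(brentq(f, lo, hi, xtol=1e-6))


def gen_toy_plan(targets, prescription: float = 1.0,
                 preset: MachinePreset = PROVISION,
                 entry_z: float = -15.0,
                 n_layers: int = 8, layer_span: tuple[float, float] = (-1.0, 0.7),
                 spot_grid: int = 7, spot_spacing: float = 0.5) -> PlanSummary:
    """Spot-scanning plan delivering ``prescription`` Gy to cubic targets.

    ``targets`` is a list of (x, y, depth) centers in cm, depth measured
    from the phantom entry plane.  Each target gets ``n_layers`` energy
    layers whose Bragg peaks span ``layer_span`` (cm, relative to the
    target depth; asymmetric because the distal fall-off is sharp while
    the proximal build-up is shallow) and a ``spot_grid`` x ``spot_grid``
    lateral spot pattern extending beyond the 1 cm target face.  Layer
    weights and per-axis spot weights are each solved by non-negative
    least squares so the depth dose is flat across the target (a
    spread-out Bragg peak) and the lateral profile is flat across the
    target face, then scaled so the dose at the target center equals the
    prescription; all spots must stay inside the 12 x 12 cm^2 field bound.
    """
    from scipy.optimize import nnls

    machine = preset.machine_model()
    mucal = machine.mu_calibration
    beamlets: list[BeamletSpec] = []
    for tx, ty, tdepth in targets:
        if abs(tx) > 6.0 or abs(ty) > 6.0:
            raise ValueError("target outside the 12 x 12 cm^2 field bound")
        peak_depths = np.linspace(tdepth + layer_span[0],
                                  tdepth + layer_span[1], n_layers)
        offs = (np.arange(spot_grid) - (spot_grid - 1) / 2.0) * spot_spacing
        # flatten the summed Bragg curves over the target depth extent
        sample_z = np.linspace(tdepth - 0.5, tdepth + 0.5, 21)
        layer_info = []
        a = np.zeros((len(sample_z), n_layers))
        for li, d in enumerate(peak_depths):
            e_nom = _energy_for_depth(preset, d, entry_z)
            e_mc = float(preset.energy_mc(e_nom))
            fwhm = float(preset.momentum_fwhm(e_nom))
            zf, idd = _idd_water(e_mc, fwhm, zmax=tdepth + 2.0)
            layer_info.append((e_nom, zf, idd))
            a[:, li] = np.interp(sample_z, zf, idd)
        w, _ = nnls(a, np.ones(len(sample_z)))

        # flatten the lateral profile across the target face per axis,
        # using the spot width of the central layer at the target depth
        z_iso_target = entry_z + tdepth  # beam-frame z of the target center
        from .transport import fermi_eyges_sigma

        e_mid = layer_info[n_layers // 2][0]
        src_mid = beamlet_origin_state(machine, e_mid, tx, ty)
        drift = z_iso_target - src_mid.origin_z
        s_mcs = float(fermi_eyges_sigma(float(preset.energy_mc(e_mid)),
                                        np.array([tdepth]))[0])
        sx_t = float(np.sqrt(src_mid.sigma_x**2
                             + (src_mid.div_x * drift) ** 2 + s_mcs**2))
        sy_t = float(np.sqrt(src_mid.sigma_y**2
                             + (src_mid.div_y * drift) ** 2 + s_mcs**2))
        sample_l = np.linspace(-0.65, 0.65, 27)

        def _axis_weights(sigma):
            b = np.exp(-0.5 * ((sample_l[:, None] - offs[None, :])
                               / sigma) ** 2)
            v, _ = nnls(b, np.ones(len(sample_l)))
            return v

        vx = _axis_weights(sx_t)
        vy = _axis_weights(sy_t)

        dose_center = 0.0  # Gy per unit global MU scale
        specs = []
        for (e_nom, zf, idd), wl in zip(layer_info, w):
            if wl <= 0:
                continue
            idd_t = float(np.interp(tdepth, zf, idd))
            k = float(mucal.k(e_nom))
            src = beamlet_origin_state(machine, e_nom, tx, ty)
            sx = float(np.hypot(src.sigma_x, src.div_x * drift))
            sy = float(np.hypot(src.sigma_y, src.div_y * drift))
            for ox, wx in zip(offs, vx):
                for oy, wy in zip(offs, vy):
                    if wx * wy <= 0:
                        continue
                    mu = float(wl * wx * wy)
                    specs.append(BeamletSpec(e_nom, mu=mu,
                                             x_iso=tx + ox, y_iso=ty + oy))
                    gx = (np.exp(-0.5 * (ox / sx) ** 2)
                          / (sx * np.sqrt(2 * np.pi)))
                    gy = (np.exp(-0.5 * (oy / sy) ** 2)
                          / (sy * np.sqrt(2 * np.pi)))
                    dose_center += (k * mu * idd_t * gx * gy
                                    * GY_PER_MEV_PER_G)
        mu_scale = prescription / dose_center
        for s in specs:
            s.mu = s.mu * mu_scale
        beamlets.extend(specs)
    return PlanSummary(fields=[PlanField(label="F1", beamlets=beamlets)],
                       label="toy_targets")


def write_rtplan(plan: PlanSummary, path, label: str | None = None) -> None:
    """Write a PlanSummary as a minimal synthetic DICOM RT Ion Plan.

    Spots are grouped into energy layers per field (paired control points,
    the closing one with zero weights), positions in mm, meterset weights
    equal to the MU values.  Synthetic fixture writer for round-trip tests.
    """
    import datetime

    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(
        "1.2.840.10008.5.1.4.1.1.481.8")  # RT Ion Plan Storage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTION"
    ds.RTPlanLabel = label or plan.label
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYN000"
    now = datetime.datetime.now()
    ds.InstanceCreationDate = now.strftime("%Y%m%d")
    ds.InstanceCreationTime = now.strftime("%H%M%S")

    ds.FractionGroupSequence = []
    ds.IonBeamSequence = []
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = []

    for bi, f in enumerate(plan.fields, start=1):
        beam = Dataset()
        beam.BeamNumber = bi
        beam.BeamName = f.label
        beam.RadiationType = "PROTON"
        beam.ScanMode = "MODULATED"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.IonControlPointSequence = []

        layers: dict[float, list[BeamletSpec]] = {}
        for b in f.beamlets:
            layers.setdefault(b.energy_nominal, []).append(b)

        total_mu = sum(b.mu for b in f.beamlets)
        if total_mu <= 0:
            raise ValueError(f"field {f.label} has zero total MU")
        cum = 0.0
        cp_index = 0
        for e in sorted(layers, reverse=True):  # high to low energy
            spots = layers[e]
            pos = []
            weights = []
            for s in spots:
                pos += [s.x_iso * 10.0, s.y_iso * 10.0]  # cm -> mm
                weights.append(s.mu)
            for closing in (False, True):
                cp = Dataset()
                cp.ControlPointIndex = cp_index
                cp.NominalBeamEnergy = e
                cp.NumberOfScanSpotPositions = len(spots)
                cp.ScanSpotPositionMap = pos
                cp.ScanSpotMetersetWeights = (
                    [0.0] * len(spots) if closing else weights)
                cp.CumulativeMetersetWeight = (
                    cum + (sum(weights) if closing else 0.0))
                beam.IonControlPointSequence.append(cp)
                cp_index += 1
            cum += sum(weights)
        beam.NumberOfControlPoints = cp_index
        beam.FinalCumulativeMetersetWeight = cum
        ds.IonBeamSequence.append(beam)

        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = total_mu
        fg.ReferencedBeamSequence.append(rb)

    ds.FractionGroupSequence.append(fg)
    ds.save_as(str(path), enforce_file_format=True)
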