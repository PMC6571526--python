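"""Forward engine: ranges, Bragg curves, 3D dose and the TPS lateral kernel."""

import numpy as np
import pytest
from scipy.integrate import quad

import pbsbeam as pb
from pbsbeam import synth
from pbsbeam.constants import GY_PER_MEV_PER_G
from pbsbeam.energy_model import peak_metrics
from pbsbeam.materials import WATER, stopping_power
from pbsbeam.mu_model import integrated_dose
from pbsbeam.transport import (
    E_CUTOFF_MEV,
    DoseGrid,
    energy_at_residual_range,
    fermi_eyges_sigma,
    highland_scattering_rate,
    penumbra_8020,
    read_dose_mhd,
    rs_style_lateral,
    water_range,
    write_dose_mhd,
)


class TestCsdaRange:
    def test_zero_at_cutoff(self):
        assert pb.csda_range(E_CUTOFF_MEV) == 0.0

    def test_fundamental_theorem(self):
        # dR/dE = 1/S(E) by construction
        h = 0.05
        deriv = (pb.csda_range(150.0 + h) - pb.csda_range(150.0 - h)) / (2 * h)
        assert deriv == pytest.approx(1.0 / stopping_power(WATER, 150.0),
                                      rel=1e-3)

    def test_monotone(self):
        es = np.linspace(50.0, 250.0, 21)
        rs = [pb.csda_range(float(e)) for e in es]
        assert all(a < b for a, b in zip(rs, rs[1:]))

    def test_quadrature_convergence(self):
        # the tabulated range must agree with adaptive quadrature closely
        assert float(water_range(160.0)) == pytest.approx(pb.csda_range(160.0),
                                                          rel=1e-4)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pb.csda_range(400.0)


class TestDepthDose:
    def test_peak_monotone_in_energy(self):
        pks = [peak_metrics(pb.depth_dose(float(e), 0.005))[0]
               for e in np.linspace(100.0, 230.0, 8)]
        assert all(a < b for a, b in zip(pks, pks[1:]))

    def test_ratio_decreases_with_spread(self):
        ratios = [peak_metrics(pb.depth_dose(160.0, s))[1]
                  for s in (0.002, 0.006, 0.010)]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_limiting_case_peak_at_csda_range(self):
        # no spread, no straggling, no nuclear term: peak at the CSDA range
        depths = np.arange(0.0, 20.0, 0.05)
        c = pb.depth_dose(160.0, 0.0, depths=depths, straggling=False,
                          nuclear=False, normalize=True)
        i = int(np.argmax(c.dose))
        assert abs(depths[i] - water_range(160.0)) <= 0.05 + 1e-9

    def test_grid_not_covering_peak_warns(self):
        with pytest.warns(UserWarning, match="peak"):
            pb.depth_dose(160.0, 0.005, depths=np.linspace(0, 10, 100))

    def test_integral_conserves_energy(self):
        # lateral-integrated curve integrates to the beam energy (no nuclear)
        c = pb.depth_dose(180.0, 0.006, normalize=False)
        dep = np.trapezoid(c.dose, c.depths)
        assert dep == pytest.approx(180.0 - E_CUTOFF_MEV, rel=0.01)


class TestFermiEyges:
    def test_matches_quadrature_oracle(self):
        # independent closed-form evaluation of the Fermi-Eyges integral
        r0 = float(water_range(160.0))

        def t_rate(u):
            e = float(energy_at_residual_range(r0 - u))
            return highland_scattering_rate(u, e)

        for z in (3.0, 8.0, 12.0):
            oracle = np.sqrt(quad(lambda u: (z - u) ** 2 * t_rate(u),
                                  0.0, z, limit=200)[0])
            mine = float(fermi_eyges_sigma(160.0, np.array([z]))[0])
            assert mine == pytest.approx(oracle, rel=0.02)

    def test_monotone_growth(self):
        z = np.linspace(0.5, 15.0, 30)
        s = fermi_eyges_sigma(160.0, z)
        assert np.all(np.diff(s) > 0)


class TestComputeDose:
    def test_zero_beamlets(self, water_box):
        grid = pb.compute_dose([], water_box)
        assert np.all(grid.dose == 0)

    def test_linearity_in_weights(self, machine, water_box):
        src1 = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0,
                                       weight_protons=1.0)
        src2 = pb.beamlet_origin_state(machine, 140.0, 2.0, 0.0,
                                       weight_protons=3.0)
        g = pb.compute_dose([src1, src2], water_box)
        # doubling every weight leaves the per-*total*-proton grid unchanged,
        # so absolute dose (x total N_p) doubles in every voxel
        abs1 = g.to_absolute(4.0)
        src1b = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0,
                                        weight_protons=2.0)
        src2b = pb.beamlet_origin_state(machine, 140.0, 2.0, 0.0,
                                        weight_protons=6.0)
        abs2 = pb.compute_dose([src1b, src2b], water_box).to_absolute(8.0)
        np.testing.assert_allclose(abs2.dose, 2 * abs1.dose, rtol=1e-12)

    def test_energy_conservation(self, machine, water_box):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0,
                                      weight_protons=1.0)
        g = pb.compute_dose([src], water_box, nuclear=False)
        expected = (src.mean_energy_mc - E_CUTOFF_MEV) * GY_PER_MEV_PER_G
        assert integrated_dose(g) == pytest.approx(expected, rel=0.01)

    def test_lateral_sigma_matches_scattering_theory(self, machine, water_box):
        # single beamlet, shallow depth: profile sigma = optics + Fermi-Eyges
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0,
                                      weight_protons=1.0)
        g = pb.compute_dose([src], water_box)
        zc = g.axis_centers(2)
        k = int(np.argmin(np.abs(zc - (-9.0))))  # 6 cm deep
        slab = g.dose[:, :, k]
        x = g.axis_centers(0)
        prof = slab.sum(axis=1)
        mu = np.sum(x * prof) / prof.sum()
        sig_fit = np.sqrt(np.sum((x - mu) ** 2 * prof) / prof.sum())
        depth = zc[k] - water_box.entry_z
        r0 = float(water_range(src.mean_energy_mc))

        def t_rate(u):
            e = float(energy_at_residual_range(r0 - u))
            return highland_scattering_rate(u, e)

        sig_mcs = np.sqrt(quad(lambda u: (depth - u) ** 2 * t_rate(u),
                               0.0, depth, limit=200)[0])
        sig_opt = src.div_x * (zc[k] - src.origin_z)
        expected = np.hypot(sig_opt, sig_mcs)
        assert sig_fit == pytest.approx(expected, rel=0.02)

    def test_off_axis_peak_on_geometric_ray(self, machine):
        ph = synth.gen_phantom("water_box", dims=(12.0, 12.0, 22.0),
                               voxel=(0.2, 0.2, 0.2), entry_z=-15.0)
        src = pb.beamlet_origin_state(machine, 160.0, 3.0, 0.0,
                                      weight_protons=1.0)
        g = pb.compute_dose([src], ph)
        # find the Bragg peak slab and its lateral maximum
        z_prof = g.dose.sum(axis=(0, 1))
        k = int(np.argmax(z_prof))
        slab = g.dose[:, :, k]
        i, j = np.unravel_index(np.argmax(slab), slab.shape)
        x = g.axis_centers(0)[i]
        zc = g.axis_centers(2)[k]
        expected_x = 3.0 * (zc - src.origin_z) / (0.0 - src.origin_z)
        assert x == pytest.approx(expected_x, abs=0.2)

    def test_sampled_agrees_with_pencil(self, machine):
        ph = synth.gen_phantom("water_box", dims=(10.0, 10.0, 20.0),
                               voxel=(0.4, 0.4, 0.4), entry_z=-15.0)
        src = pb.beamlet_origin_state(machine, 150.0, 0.0, 0.0,
                                      weight_protons=1.0)
        pencil = pb.compute_dose([src], ph)
        sampled = pb.compute_dose([src], ph, mode="sampled", seed=3,
                                  n_samples=400_000)
        sel = sampled.uncertainty > 0
        diff = np.abs(sampled.dose - pencil.dose)[sel]
        # fraction of voxels outside 3 sigma should be small
        frac_bad = np.mean(diff > 3 * sampled.uncertainty[sel])
        assert frac_bad < 0.05

    def test_sampled_determinism(self, machine):
        ph = synth.gen_phantom("water_box", dims=(8.0, 8.0, 20.0),
                               voxel=(0.5, 0.5, 0.5), entry_z=-15.0)
        src = pb.beamlet_origin_state(machine, 150.0, 0.0, 0.0,
                                      weight_protons=1.0)
        a = pb.compute_dose([src], ph, mode="sampled", seed=9, n_samples=5000)
        b = pb.compute_dose([src], ph, mode="sampled", seed=9, n_samples=5000)
        np.testing.assert_array_equal(a.dose, b.dose)


class TestRsKernel:
    def test_component_count_and_normalization(self):
        r, prof = rs_style_lateral(0.5)
        integral = np.trapezoid(prof * 2 * np.pi * r, r)
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_collapse_to_single_gaussian(self):
        s = 0.4
        r, prof = rs_style_lateral(s, {"r1": 0.0, "r2": 0.0})
        # second moment of a 2D Gaussian radial profile is 2 sigma^2
        m2 = np.trapezoid(prof * 2 * np.pi * r**3, r)
        assert m2 == pytest.approx(2 * s**2, rel=1e-3)

    def test_wider_penumbra_than_single_gaussian(self):
        s = 0.5
        r, p19 = rs_style_lateral(s)
        r1, p1 = rs_style_lateral(s, {"w1": 0.0, "w2": 0.0,
                                      "r1": 0.0, "r2": 0.0})
        assert penumbra_8020(r, p19) > penumbra_8020(r1, p1)

    def test_negative_radius_errors(self):
        with pytest.raises(ValueError):
            rs_style_lateral(0.5, {"r1": -1.0})


def test_mhd_round_trip(tmp_path, rng):
    grid = DoseGrid(rng.random((6, 7, 8)), (0.2, 0.3, 0.4),
                    (-1.0, -2.0, -3.0), "absolute")
    write_dose_mhd(grid, tmp_path / "dose.mhd")
    back = read_dose_mhd(tmp_path / "dose.mhd")
    np.testing.assert_allclose(back.dose, grid.dose, rtol=1e-6)
    np.testing.assert_allclose(back.voxel_size, grid.voxel_size)
    np.testing.assert_allclose(back.origin, grid.origin, atol=1e-6)
    assert back.normalization == "absolute"
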