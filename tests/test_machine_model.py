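"""Virtual-source geometry, optics back-projection and beamlet states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pbsbeam as pb
from pbsbeam import synth
from pbsbeam.machine_model import (
    MachineModel,
    SpotMeasurement,
    load_machine,
    read_spot_csv,
    save_machine,
    write_spot_csv,
)


def _spots_linear(z_source, div, zs, energy=160.0, axis_both=True):
    """Spots growing linearly from a point focus on both axes."""
    return [SpotMeasurement(energy, z, div * (z - z_source),
                            div * (z - z_source)) for z in zs]


class TestFitVirtualSource:
    def test_exact_linear_intercept(self):
        # sigma(z) = 0.01 (z + 100) vanishes at z = -100
        spots = _spots_linear(-100.0, 0.01, [-20.0, 0.0, 20.0])
        assert pb.fit_virtual_source(spots, "X") == pytest.approx(-100.0)
        assert pb.fit_virtual_source(spots, "Y") == pytest.approx(-100.0)

    def test_provision_preset_recovery(self, preset):
        spots = synth.gen_spot_measurements(preset, [160.0])
        zx = pb.fit_virtual_source(spots, "X")
        zy = pb.fit_virtual_source(spots, "Y")
        assert zx == pytest.approx(-193.5, rel=1e-6)
        assert zy == pytest.approx(-231.5, rel=1e-6)

    def test_noisy_fit_matches_normal_equations(self, rng):
        # single energy: shared-intercept LS reduces to the plain line fit
        zs = np.linspace(-20, 20, 20)
        sig = 0.004 * (zs + 180.0) + rng.normal(0, 1e-3, 20)
        spots = [SpotMeasurement(160.0, z, s, s) for z, s in zip(zs, sig)]
        # closed-form normal equations for sigma = a z + b
        n = len(zs)
        sx, sy_ = zs.sum(), sig.sum()
        sxx, sxy = (zs * zs).sum(), (zs * sig).sum()
        a = (n * sxy - sx * sy_) / (n * sxx - sx * sx)
        b = (sy_ - a * sx) / n
        assert pb.fit_virtual_source(spots, "X") == pytest.approx(-b / a,
                                                                  abs=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(z0=st.floats(-400, -60), div=st.floats(5e-4, 2e-2))
    def test_recovery_property(self, z0, div):
        spots = _spots_linear(z0, div, [-20.0, -10.0, 0.0, 10.0, 20.0])
        assert abs(pb.fit_virtual_source(spots, "X") / z0 - 1) <= 1e-3

    def test_pooled_energies(self, preset):
        spots = synth.gen_spot_measurements(preset, [100.0, 160.0, 220.0])
        assert pb.fit_virtual_source(spots, "Y") == pytest.approx(-231.5,
                                                                  rel=1e-3)

    def test_single_plane_errors(self):
        spots = [SpotMeasurement(160.0, 0.0, 0.5, 0.5)] * 3
        with pytest.raises(ValueError, match="distinct planes"):
            pb.fit_virtual_source(spots, "X")

    def test_converging_beam_errors(self):
        spots = [SpotMeasurement(160.0, z, 0.5 - 0.01 * z, 0.5 - 0.01 * z)
                 for z in (-20.0, 0.0, 20.0)]
        with pytest.raises(ValueError, match="converging|slope"):
            pb.fit_virtual_source(spots, "X")


class TestFitOptics:
    def test_forward_generate_then_invert(self):
        # quadrature drift truth must be recovered exactly
        s0y, divy, divx = 0.25, 3e-3, 3.5e-3
        z0 = -193.5
        zs = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
        spots = [SpotMeasurement(160.0, z,
                                 divx * (z - z0),
                                 np.hypot(s0y, divy * (z - z0)))
                 for z in zs]
        opt = pb.fit_optics(spots, z0, order=3)
        assert float(opt.sigma_y(160.0)) == pytest.approx(s0y, abs=1e-6)
        assert float(opt.div_y(160.0)) == pytest.approx(divy, abs=1e-9)
        assert float(opt.div_x(160.0)) == pytest.approx(divx, abs=1e-9)
        assert float(opt.sigma_x(160.0)) == 0.0

    def test_zero_divergence(self):
        spots = [SpotMeasurement(160.0, z, 1e-6, 0.4)
                 for z in (-20.0, 0.0, 20.0)]
        opt = pb.fit_optics(spots, -193.5, order=1)
        assert float(opt.div_y(160.0)) == pytest.approx(0.0, abs=1e-9)
        assert float(opt.sigma_y(160.0)) == pytest.approx(0.4, abs=1e-9)

    def test_provision_anisotropy(self, machine):
        # div_x slightly larger than div_y; the opposite for the spot sigma
        e = np.linspace(100, 220, 5)
        assert np.all(machine.optics.div_x(e) > machine.optics.div_y(e))
        assert np.all(machine.optics.sigma_y(e)
                      > np.atleast_1d(machine.optics.sigma_x(e)))

    def test_order_too_high_errors(self, preset):
        spots = synth.gen_spot_measurements(preset, [100.0, 160.0])
        with pytest.raises(ValueError, match="order"):
            pb.fit_optics(spots, -193.5, order=3)


class TestBeamletState:
    def test_on_axis_direction(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        np.testing.assert_allclose(src.direction, [0.0, 0.0, 1.0], atol=1e-12)

    def test_off_axis_direction(self, machine):
        machine2 = MachineModel(z_vsad_x=-193.5, z_vsad_y=-231.5,
                                optics=machine.optics)
        src = pb.beamlet_origin_state(machine2, 160.0, 10.0, 0.0)
        # normalize (10, 0, 193.5) by hand: norm = 193.7581...
        np.testing.assert_allclose(src.direction,
                                   [0.0516107, 0.0, 0.9986673], atol=1e-6)

    def test_line_source(self, machine):
        for e in (98.0, 160.0, 230.0):
            assert pb.beamlet_origin_state(machine, e, 1.0, -2.0).sigma_x == 0.0

    def test_energy_limit_error(self, machine):
        with pytest.raises(ValueError, match="lower"):
            pb.beamlet_origin_state(machine, 50.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="upper"):
            pb.beamlet_origin_state(machine, 250.0, 0.0, 0.0)

    def test_circular_at_isocenter(self, machine):
        for e in (110.0, 160.0, 210.0):
            src = pb.beamlet_origin_state(machine, e, 0.0, 0.0)
            sx, sy = pb.spot_sigma_at_z(src, 0.0)
            assert abs(sx - sy) / sy < 0.05

    def test_two_plane_steering_offsets_y(self, machine):
        machine.steering = "two_plane"
        try:
            src = pb.beamlet_origin_state(machine, 160.0, 0.0, 5.0)
            assert src.center_y > 0
            # the ray still passes through the isocenter spot position
            y_iso = (src.center_y
                     + src.direction[1] / src.direction[2] * (0 - src.origin_z))
            assert y_iso == pytest.approx(5.0, abs=1e-9)
        finally:
            machine.steering = "single_origin"


class TestSpotSigma:
    def test_zero_divergence_constant(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        src.div_x = src.div_y = 0.0
        sx0, sy0 = pb.spot_sigma_at_z(src, src.origin_z)
        sx1, sy1 = pb.spot_sigma_at_z(src, 0.0)
        assert sx0 == sx1 and sy0 == sy1

    def test_pure_drift(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        src.sigma_x = src.sigma_y = 0.0
        src.div_x = src.div_y = 1e-3
        sx, _ = pb.spot_sigma_at_z(src, src.origin_z + 100.0)
        assert sx == pytest.approx(0.1)

    def test_monotone_in_z(self, machine):
        src = pb.beamlet_origin_state(machine, 130.0, 0.0, 0.0)
        zs = np.linspace(src.origin_z, 20.0, 50)
        sx, sy = pb.spot_sigma_at_z(src, zs)
        assert np.all(np.diff(sx) >= 0) and np.all(np.diff(sy) >= 0)

    def test_upstream_errors(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            pb.spot_sigma_at_z(src, src.origin_z - 1.0)


class TestSamplePhaseSpace:
    def test_moments(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        n = 100_000
        ps = pb.sample_phase_space(src, n, seed=7)
        var = ps["y"].var()
        se = src.sigma_y**2 * np.sqrt(2.0 / (n - 1))  # SE of sample variance
        assert abs(var - src.sigma_y**2) < 3 * se
        assert ps["x"].std() == pytest.approx(0.0)  # line source

    def test_zero_spread_energies_identical(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        src.momentum_fwhm_fraction = 0.0
        ps = pb.sample_phase_space(src, 100, seed=0)
        assert np.all(ps["energy"] == ps["energy"][0])

    def test_seed_determinism(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 1.0, 1.0)
        a = pb.sample_phase_space(src, 1000, seed=42)
        b = pb.sample_phase_space(src, 1000, seed=42)
        for key in ("x", "y", "energy"):
            np.testing.assert_array_equal(a[key], b[key])

    def test_unit_directions(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 3.0, -2.0)
        ps = pb.sample_phase_space(src, 500, seed=1)
        np.testing.assert_allclose(np.linalg.norm(ps["direction"], axis=1),
                                   1.0, atol=1e-12)

    def test_invalid_n(self, machine):
        src = pb.beamlet_origin_state(machine, 160.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            pb.sample_phase_space(src, 0)


class TestSerialization:
    def test_machine_round_trip(self, machine, tmp_path):
        path = tmp_path / "machine.json"
        save_machine(machine, path)
        m2 = load_machine(path)
        assert m2.z_vsad_x == pytest.approx(machine.z_vsad_x)
        assert m2.z_vsad_y == pytest.approx(machine.z_vsad_y)
        e = np.linspace(*machine.energy_limits, 7)
        np.testing.assert_allclose(m2.optics.sigma_y(e),
                                   machine.optics.sigma_y(e))
        np.testing.assert_allclose(m2.energy_calibration.energy_mc(e),
                                   machine.energy_calibration.energy_mc(e))
        np.testing.assert_allclose(m2.mu_calibration.k(e),
                                   machine.mu_calibration.k(e))

    def test_bad_format_tag(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something/9"}')
        with pytest.raises(ValueError, match="format"):
            load_machine(path)

    def test_spot_csv_round_trip(self, preset, tmp_path):
        spots = synth.gen_spot_measurements(preset, [100.0, 160.0])
        path = tmp_path / "spots.csv"
        write_spot_csv(spots, path)
        back = read_spot_csv(path)
        assert back == spots

    def test_spot_csv_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("energy_MeV,z_cm\n100,0\n")
        with pytest.raises(ValueError, match="sigma_x_cm"):
            read_spot_csv(path)
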