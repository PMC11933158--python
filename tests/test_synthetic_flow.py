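import math

import numpy as np
import pytest

from conftest import Q_REF
from pisaflow.geometry import make_orifice
from pisaflow.synthetic_flow import (FieldSeries, JetSpec, SinkFlowSpec,
                                     VelocityField, Waveform,
                                     aperture_axial_profile,
                                     confined_sink_field, default_phases,
                                     hemisphere_flux, jet_exit_series,
                                     piv_sample, point_sink_field,
                                     pulse_waveform, ray_speed_profile,
                                     sink_sheet_field, sink_sheet_panels,
                                     _sink_sheet_velocity)


class TestVelocityField:
    def test_rejects_bad_axes_and_shapes(self):
        x = np.array([0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            VelocityField(x, np.array([0.0, 1.0]), np.zeros((3, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            VelocityField(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                          np.zeros((3, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            VelocityField(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                          np.full((2, 2), np.nan), np.zeros((2, 2)))

    def test_series_requires_shared_grid(self):
        x = np.array([0.0, 1.0]); y = np.array([0.0, 1.0])
        f1 = VelocityField(x, y, np.zeros((2, 2)), np.zeros((2, 2)))
        f2 = VelocityField(x + 1, y, np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            FieldSeries(np.array([0.0, 10.0]), [f1, f2])


class TestPointSink:
    def test_on_axis_speed(self, sink_field):
        # speed Q/(2 pi R^2): 20 cm/s at the radius that maps Va=20 to Q
        R = math.sqrt(Q_REF / (2 * math.pi * 20.0))
        i = np.argmin(np.abs(sink_field.x + R))
        j = np.argmin(np.abs(sink_field.y))
        speed = np.hypot(sink_field.u[i, j], sink_field.v[i, j])
        assert speed == pytest.approx(Q_REF / (2 * math.pi * sink_field.x[i]**2), rel=1e-9)
        assert speed == pytest.approx(20.0, rel=1e-2)  # nearest-node R

    def test_velocity_antiparallel_to_position(self, sink_grid):
        f = point_sink_field(Q_REF, *sink_grid)
        X, Y = np.meshgrid(f.x, f.y, indexing="ij")
        dot = f.u * X + f.v * Y
        mag = np.hypot(f.u, f.v) * np.hypot(X, Y)
        assert np.allclose(dot, -mag, rtol=1e-12)

    def test_hemisphere_flux_conservation(self):
        def vel(pts):
            r2 = (pts**2).sum(axis=1, keepdims=True)
            return -Q_REF / (2 * math.pi * r2) * pts / np.sqrt(r2)
        for radius in (0.5, 1.5, 3.0):
            assert hemisphere_flux(vel, radius) == pytest.approx(Q_REF, rel=2e-3)

    def test_singularity_guard(self):
        with pytest.raises(ValueError):
            point_sink_field(Q_REF, np.arange(-1.0, 0.001, 0.05),
                             np.arange(-0.5, 0.501, 0.05))

    def test_divergence_free_interior_3d(self):
        ax = np.arange(-2.0, -0.799, 0.05)
        tr = np.arange(-0.5, 0.501, 0.05)
        f = point_sink_field(Q_REF, ax, tr, tr)
        du = np.gradient(f.u, f.x, axis=0)
        dv = np.gradient(f.v, f.y, axis=1)
        dw = np.gradient(f.w, f.z, axis=2)
        div = (du + dv + dw)[1:-1, 1:-1, 1:-1]
        local = (np.abs(du) + np.abs(dv) + np.abs(dw))[1:-1, 1:-1, 1:-1]
        assert np.abs(div / local).max() < 0.01


class TestAperture:
    def test_orifice_plane_value(self):
        assert aperture_axial_profile(Q_REF, 0.61, 0.0) == pytest.approx(
            Q_REF / (2 * math.pi * 0.61**2), rel=1e-12)

    def test_far_field_is_point_sink(self):
        x = 50.0
        ratio = aperture_axial_profile(Q_REF, 0.61, x) / (Q_REF / (2 * math.pi * x**2))
        assert ratio == pytest.approx(1.0, abs=2e-4)

    def test_inverse_radius_for_20cm_s(self):
        x = math.sqrt(Q_REF / (2 * math.pi * 20.0) - 0.61**2)
        assert aperture_axial_profile(Q_REF, 0.61, x) == pytest.approx(20.0, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            aperture_axial_profile(Q_REF, -1.0, 0.5)
        with pytest.raises(ValueError):
            aperture_axial_profile(Q_REF, 0.5, -0.1)


class TestSinkSheet:
    def test_far_field_matches_point_sink(self, circle_L):
        prof = ray_speed_profile(SinkFlowSpec(circle_L, Q_REF, model="sink_sheet"))
        s = 10 * circle_L.equivalent_radius_cm
        assert prof(np.array([s]))[0] == pytest.approx(
            Q_REF / (2 * math.pi * s**2), rel=0.02)

    def test_hemisphere_flux_conserved_all_shapes(self):
        for shape, h, w in [("circle", 12.2, None), ("slit", 7.3, 22.9)]:
            orf = make_orifice(shape, h, w)
            cents, strengths = sink_sheet_panels(orf, Q_REF, 512)
            vel = lambda pts: _sink_sheet_velocity(pts, cents, strengths)
            for radius in (1.5, 3.0):
                assert hemisphere_flux(vel, radius) == pytest.approx(Q_REF, rel=0.01)

    def test_wall_normal_zero_outside_orifice(self, circle_L):
        cents, strengths = sink_sheet_panels(circle_L, Q_REF, 256)
        pts = np.array([[0.0, 1.5, 0.0], [0.0, 0.0, -2.0], [0.0, 1.1, 1.1]])
        vel = _sink_sheet_velocity(pts, cents, strengths)
        assert np.allclose(vel[:, 0], 0.0, atol=1e-12)

    def test_axial_profile_matches_uniform_disk_closed_form(self, circle_L):
        # the uniform-strength sheet equals the uniform sink disk:
        # u(s) = sigma (1 - s / sqrt(s^2 + R^2)); the exact-aperture
        # profile is only reached in the far field (within 5% beyond
        # ~2.5 radii), the near field differing by the uniform-vs-exact
        # strength density
        a = circle_L.equivalent_radius_cm
        sigma = Q_REF / circle_L.area_cm2
        prof = ray_speed_profile(SinkFlowSpec(circle_L, Q_REF, model="sink_sheet"))
        s = np.array([a / 2, a, 2 * a, 2.5 * a, 4 * a])
        disk = sigma * (1 - s / np.hypot(s, a))
        assert np.allclose(prof(s), disk, rtol=0.02)
        ap = aperture_axial_profile(Q_REF, a, s[3:])
        assert np.allclose(prof(s[3:]), ap, rtol=0.05)

    def test_standoff_violation_raises(self, circle_L):
        with pytest.raises(ValueError):
            sink_sheet_field(circle_L, Q_REF, np.array([-0.001, 0.0]),
                             np.arange(-0.2, 0.201, 0.1))


class TestConfinedSink:
    def test_order_zero_identical_to_free_field(self, circle_L, sink_grid):
        spec = SinkFlowSpec(circle_L, Q_REF, chamber_halfwidth=2.0, image_order=0)
        free = point_sink_field(Q_REF, *sink_grid)
        conf = confined_sink_field(spec, *sink_grid)
        assert np.array_equal(conf.u, free.u) and np.array_equal(conf.v, free.v)

    def test_speed_increases_with_image_order(self, circle_L, sink_grid):
        speeds = []
        for order in (0, 1, 2):
            spec = SinkFlowSpec(circle_L, Q_REF, chamber_halfwidth=2.0,
                                image_order=order)
            f = confined_sink_field(spec, *sink_grid)
            speeds.append(np.hypot(f.u, f.v)[0, len(f.y) // 2])  # far corner, on axis
        assert speeds[0] < speeds[1] < speeds[2]

    def test_confined_profile_above_free_profile(self, circle_L):
        free = ray_speed_profile(SinkFlowSpec(circle_L, Q_REF, model="aperture_exact"))
        conf = ray_speed_profile(SinkFlowSpec(circle_L, Q_REF, model="aperture_exact",
                                              chamber_halfwidth=2.0, image_order=3))
        s = np.linspace(0.5, 3.0, 20)
        assert np.all(conf(s) > free(s))


class TestWaveform:
    def test_peaks_and_support(self):
        w = Waveform()
        assert pulse_waveform(w, w.t_global_peak) == pytest.approx(w.U_global)
        assert pulse_waveform(w, 100.0) == 0.0
        assert pulse_waveform(w, 600.0) == 0.0

    def test_local_peak_is_strict_local_max(self):
        w = Waveform()
        t = np.array([w.t_local_peak - 1, w.t_local_peak, w.t_local_peak + 1])
        u = pulse_waveform(w, t)
        assert u[1] > u[0] and u[1] > u[2]
        assert u[1] == pytest.approx(w.U_local)

    def test_exponential_tail_time_constant(self):
        w = Waveform()
        t1, t2 = 350.0, 400.0
        u1, u2 = pulse_waveform(w, np.array([t1, t2]))
        # far from the smoothed onset the decay is exp(-(t - tg)/tau)
        assert np.log(u1 / u2) == pytest.approx((t2 - t1) / w.decay_tau, rel=0.02)

    def test_integral_matches_dense_trapezoid(self):
        w = Waveform()
        t = np.linspace(0.0, 750.0, 200_001)
        dense = np.trapezoid(pulse_waveform(w, t), t) * 1e-3
        assert w.integral() == pytest.approx(dense, rel=1e-6)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            Waveform(t_local_peak=250.0, t_global_peak=245.0)


class TestJetExit:
    def test_block_profile_when_beta_zero(self, circle_L):
        jet = JetSpec(circle_L, beta=0.0, taper_mm=0.0)
        x = np.array([0.0, 0.1]); y = np.arange(-0.85, 0.8501, 0.0125)
        s = jet_exit_series(jet, x, y, phases=np.array([245.0]))
        u = s.fields[0].u[0]
        inside = np.abs(y) < 0.55
        assert np.allclose(u[inside], u[inside][0])

    def test_saddle_center_to_max_ratio(self, circle_L):
        jet = JetSpec(circle_L, beta=0.3, taper_mm=0.0)
        x = np.array([0.0, 0.1]); y = np.arange(-0.85, 0.8501, 0.0025)
        s = jet_exit_series(jet, x, y, phases=np.array([245.0]))
        u = s.fields[0].u[0]
        ratio = u[np.argmin(np.abs(y))] / u.max()
        assert ratio == pytest.approx(1 / 1.3, rel=0.02)

    def test_programmed_rvol_rectangular_pulse(self):
        # U = 100 cm/s over 0.3 s through 1 cm^2 -> 30 ml; approximate the
        # rectangle by a long plateau waveform and check the closed-form
        # integral scales exactly with area and speed
        orf = make_orifice("circle", 11.283791671)  # area 1.0000 cm^2
        assert orf.area_cm2 == pytest.approx(1.0, rel=1e-9)
        w = Waveform()
        jet = JetSpec(orf, w)
        x = np.array([0.0, 0.1]); y = np.arange(-0.85, 0.8501, 0.025)
        s = jet_exit_series(jet, x, y)
        assert s.programmed_rvol == pytest.approx(orf.area_cm2 * w.integral(),
                                                  rel=1e-12)
        assert s.programmed_rvol == pytest.approx(w.integral(), rel=1e-8)

    def test_grid_must_cover_orifice(self, circle_L):
        with pytest.raises(ValueError):
            jet_exit_series(JetSpec(circle_L), np.array([0.0, 0.1]),
                            np.arange(-0.4, 0.401, 0.02))


class TestPivSample:
    def test_noise_free_single_frame_is_interpolated_truth(self, circle_jet_30ml):
        _, series = circle_jet_30ml
        ens = piv_sample(series, 0.05323, 0.0, 1, seed=0)
        mean = ens.mean_series()
        # spot-check against direct interpolation of the native field
        from scipy.interpolate import RegularGridInterpolator
        f = series.fields[20]
        interp = RegularGridInterpolator(f.axes, f.u)
        pts = np.stack(np.meshgrid(*mean.grid.axes, indexing="ij"), axis=-1)
        assert np.allclose(mean.fields[20].u, interp(pts.reshape(-1, 2)).reshape(
            mean.grid.shape), atol=1e-10)

    def test_same_seed_bit_identical(self, circle_jet_30ml):
        _, series = circle_jet_30ml
        e1 = piv_sample(series, 0.05323, 5.0, 4, seed=7)
        e2 = piv_sample(series, 0.05323, 5.0, 4, seed=7)
        assert np.array_equal(e1.frames, e2.frames)
        e3 = piv_sample(series, 0.05323, 5.0, 4, seed=8)
        assert not np.array_equal(e1.frames, e3.frames)

    def test_ensemble_mean_error_shrinks_like_sqrt_n(self, circle_jet_30ml):
        _, series = circle_jet_30ml
        sd = 5.0
        devs = {}
        for n in (4, 64):
            ens = piv_sample(series, 0.05323, sd, n, seed=3)
            truth = piv_sample(series, 0.05323, 0.0, 1, seed=3).frames[:, 0]
            dev = ens.frames.mean(axis=1) - truth
            devs[n] = dev.std()
        assert devs[4] / devs[64] == pytest.approx(4.0, rel=0.15)

    def test_spacing_coarser_than_native_required(self, circle_jet_30ml):
        _, series = circle_jet_30ml
        with pytest.raises(ValueError):
            piv_sample(series, 0.001, 0.0, 1, seed=0)
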