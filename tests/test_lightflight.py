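"""Pump-probe Kerr-gate simulator: pulse kinematics, gate response,
frame formation."""

import numpy as np
import pytest
from scipy.integrate import quad

from framecodec import (
    C_MM_PER_FS,
    GridSpec,
    KerrMediumSpec,
    PulseSpec,
    ValidationError,
    axial_profile,
    frame_signal,
    gate_response,
    pump_intensity,
    simulate_sequence,
)
from framecodec.errors import GridTooCoarseError

CS2_INDEX = 1.63
V_CS2 = C_MM_PER_FS / CS2_INDEX


def thin_slab(nx=250, ny=16, nz=40, lx=7.0, lz=0.2, tau=0.0, waist=0.05):
    """A thin Kerr slab with matching grid, pump along x, for fast runs."""
    ly = lx * ny / nx
    medium = KerrMediumSpec(tau_relax=tau, extent=(lx, ly, lz))
    grid = GridSpec(shape=(nx, ny, nz), voxel=(lx / nx, ly / ny, lz / nz))
    pump = PulseSpec(duration_fwhm=125.0, speed=V_CS2, waist=waist)
    return pump, medium, grid


def column_centroid(frame):
    prof = axial_profile(frame, "columns")
    x = np.arange(len(prof))
    return float((prof * x).sum() / prof.sum())


class TestPumpIntensity:
    def test_peak_rides_with_the_pulse_center(self):
        pump, medium, _ = thin_slab()
        for t in (0.0, 5000.0, 19000.0):
            xi = pump.speed * t  # on-axis point at the pulse center
            point = (xi, medium.extent[1] / 2, medium.extent[2] / 2)
            assert pump_intensity(pump, medium, point, t) == pytest.approx(
                pump.energy
            )

    def test_centroid_translates_rigidly(self):
        pump, medium, _ = thin_slab(lx=7.0)
        xs = np.linspace(0.0, 7.0, 4001)
        pts = np.stack(
            [xs, np.full_like(xs, medium.extent[1] / 2),
             np.full_like(xs, medium.extent[2] / 2)], axis=-1
        )
        t0, t1 = 15000.0, 15800.0
        c0 = (pump_intensity(pump, medium, pts, t0) * xs).sum() / (
            pump_intensity(pump, medium, pts, t0).sum()
        )
        c1 = (pump_intensity(pump, medium, pts, t1) * xs).sum() / (
            pump_intensity(pump, medium, pts, t1).sum()
        )
        assert c1 - c0 == pytest.approx(pump.speed * (t1 - t0), rel=1e-9)

    def test_light_travels_23_microns_in_125_fs_in_cs2(self):
        advance_mm = V_CS2 * 125.0
        assert round(advance_mm * 1000) == 23


class TestGateResponse:
    def test_delta_kernel_limit_recovers_pump_intensity(self):
        pump, _, _ = thin_slab()
        medium = KerrMediumSpec(tau_relax=1e-3, extent=(7.0, 0.5, 0.2))
        point = (3.5, 0.25, 0.1)
        t_peak = pump.t0 + 3.5 / pump.speed
        g = gate_response(pump, medium, point, t_peak)
        i = pump_intensity(pump, medium, point, t_peak)
        assert g == pytest.approx(i, rel=1e-6)
        # exact tau = 0 branch
        medium0 = KerrMediumSpec(tau_relax=0.0, extent=(7.0, 0.5, 0.2))
        ts = t_peak + np.linspace(-200, 200, 9)
        np.testing.assert_allclose(
            gate_response(pump, medium0, point, ts),
            pump_intensity(pump, medium0, point, ts),
            rtol=1e-12,
        )

    def test_matches_quadrature_of_the_relaxation_integral(self):
        """The closed-form exponentially modified Gaussian equals the
        defining convolution integral, computed by adaptive quadrature."""
        pump, _, _ = thin_slab()
        tau = 1600.0
        medium = KerrMediumSpec(tau_relax=tau, extent=(7.0, 0.5, 0.2))
        point = (3.5, 0.25, 0.1)
        tc = pump.t0 + 3.5 / pump.speed
        sigma = pump.sigma_t
        amp = pump_intensity(pump, medium, point, tc)
        for t in tc + np.array([-300.0, -50.0, 0.0, 120.0, 900.0, 4000.0]):
            expected, _ = quad(
                lambda tp: amp
                * np.exp(-0.5 * ((tp - tc) / sigma) ** 2)
                * np.exp(-(t - tp) / tau) / tau,
                tc - 40 * sigma, t, limit=500,
                epsabs=1e-300, epsrel=1e-13,
            )
            assert gate_response(pump, medium, point, float(t)) == (
                pytest.approx(expected, rel=1e-8)
            )

    def test_tail_decays_at_the_relaxation_rate(self):
        pump, _, _ = thin_slab()
        tau = 1600.0
        medium = KerrMediumSpec(tau_relax=tau, extent=(7.0, 0.5, 0.2))
        point = (1.0, 0.25, 0.1)
        tc = pump.t0 + 1.0 / pump.speed
        t1, t2 = tc + 9000.0, tc + 10000.0
        g1 = gate_response(pump, medium, point, t1)
        g2 = gate_response(pump, medium, point, t2)
        slope = (np.log(g2) - np.log(g1)) / (t2 - t1)
        assert slope == pytest.approx(-1.0 / tau, rel=1e-6)


class TestFrameSignal:
    def test_no_pump_read_overlap_gives_empty_frame(self):
        pump, medium, grid = thin_slab()
        # read crosses the slab ~50 ps before the pump arrives
        early = PulseSpec(duration_fwhm=125.0, t0=-50000.0,
                          direction=(0, 0, 1), speed=medium.speed)
        late = PulseSpec(duration_fwhm=125.0, t0=3.5 / pump.speed,
                         direction=(0, 0, 1), speed=medium.speed)
        silent = frame_signal(pump, early, medium, grid)
        active = frame_signal(pump, late, medium, grid)
        assert silent.pixels.max() <= 1e-12 * active.pixels.max()

    def test_linearity_in_read_energy(self):
        pump, medium, grid = thin_slab()
        kw = dict(duration_fwhm=125.0, t0=3.5 / pump.speed,
                  direction=(0, 0, 1), speed=medium.speed)
        a = frame_signal(pump, PulseSpec(energy=1.0, **kw), medium, grid)
        b = frame_signal(pump, PulseSpec(energy=2.0, **kw), medium, grid)
        np.testing.assert_allclose(b.pixels, 2.0 * a.pixels, rtol=1e-12)

    def test_streak_advances_three_pixels_per_125_fs_on_detector_grid(self):
        """On a 7 mm / 1002-pixel detector, 125 fs of travel in CS2 moves
        the streak by ~23 um = 3 pixels (nearest integer)."""
        pump, medium, grid = thin_slab(nx=1002, ny=16, nz=40)
        base = 3.2 / pump.speed
        frames = simulate_sequence(pump, [base, base + 125.0], medium, grid)
        shift_px = column_centroid(frames[1]) - column_centroid(frames[0])
        assert round(shift_px) == 3
        # and the physical shift is the 23 um the medium speed dictates
        assert shift_px * grid.voxel[0] == pytest.approx(V_CS2 * 125.0,
                                                         rel=1e-6)

    def test_coarse_z_grid_is_rejected(self):
        pump, medium, _ = thin_slab()
        grid = GridSpec(shape=(250, 16, 4),
                        voxel=(7.0 / 250, 7.0 * 16 / 250 / 16, 0.2 / 4))
        read = PulseSpec(duration_fwhm=125.0, direction=(0, 0, 1),
                         speed=medium.speed)
        with pytest.raises(GridTooCoarseError):
            frame_signal(pump, read, medium, grid)

    def test_grid_refinement_convergence(self):
        """Halving the z voxel and the time step changes the frame by
        less than 1% (Richardson-style check)."""
        pump, medium, _ = thin_slab()
        read_t0 = 3.5 / pump.speed

        def run(nz, oversamp):
            grid = GridSpec(shape=(250, 16, nz),
                            voxel=(7.0 / 250, 7.0 * 16 / 250 / 16, 0.2 / nz))
            read = PulseSpec(duration_fwhm=125.0, t0=read_t0,
                             direction=(0, 0, 1), speed=medium.speed)
            return frame_signal(pump, read, medium, grid,
                                time_oversampling=oversamp).pixels

        coarse = run(40, 10)
        fine = run(80, 20)
        assert np.abs(fine - coarse).max() <= 0.01 * fine.max()


class TestSimulateSequence:
    def test_frame_rate_is_reciprocal_delay_spacing(self):
        # 200 fs spacing <-> 5 THz; 1000 fs <-> 1 THz; the pulse duration
        # caps the usable rate at 1/125 fs ~ 8 THz
        assert 1.0 / 200e-15 == pytest.approx(5e12)
        assert 1.0 / 1000e-15 == pytest.approx(1e12)
        assert 1.0 / 125e-15 == pytest.approx(8e12)

    def test_nonincreasing_delays_rejected(self):
        pump, medium, grid = thin_slab()
        with pytest.raises(ValidationError):
            simulate_sequence(pump, [0.0, 0.0], medium, grid)

    def test_frames_are_translates_without_relaxation(self):
        """tau = 0: cross-correlation of successive axial profiles peaks
        at the pixel shift corresponding to the pump advance."""
        pump, medium, grid = thin_slab(nx=500)
        base = 3.0 / pump.speed
        dt = 500.0
        frames = simulate_sequence(pump, [base, base + dt], medium, grid)
        p0 = axial_profile(frames[0], "columns")
        p1 = axial_profile(frames[1], "columns")
        xcorr = np.correlate(p1, p0, mode="full")
        lag = int(np.argmax(xcorr)) - (len(p0) - 1)
        expected_px = pump.speed * dt / grid.voxel[0]
        assert lag == round(expected_px)

    def test_streak_speed_recovers_pump_speed(self):
        """Linear fit of the streak centroid over four frames returns the
        pump group speed to 0.1%."""
        pump, medium, grid = thin_slab(nx=500)
        base = 2.5 / pump.speed
        delays = [base + k * 500.0 for k in range(4)]
        frames = simulate_sequence(pump, delays, medium, grid)
        cents = np.array([column_centroid(f) for f in frames]) * grid.voxel[0]
        slope = np.polyfit(delays, cents, 1)[0]
        assert slope == pytest.approx(pump.speed, rel=1e-3)

    def test_relaxation_adds_a_trailing_skirt(self):
        """Finite tau leaves gated signal behind the pump: at every
        position behind the streak front the tau > 0 profile exceeds the
        instantaneous-gate profile, and total signal grows with tau."""
        delays = None
        profs = {}
        totals = {}
        for tau in (0.0, 400.0, 1600.0):
            pump, medium, grid = thin_slab(tau=tau)
            if delays is None:
                delays = [3.5 / pump.speed]
            frame = simulate_sequence(pump, delays, medium, grid)[0]
            profs[tau] = axial_profile(frame, "columns")
            totals[tau] = float(frame.pixels.sum())
        centroid_px = int(
            np.round((profs[0.0] * np.arange(len(profs[0.0]))).sum()
                     / profs[0.0].sum())
        )
        behind = slice(0, centroid_px - 5)
        assert np.all(profs[400.0][behind] >= profs[0.0][behind])
        assert np.all(profs[1600.0][behind] >= profs[400.0][behind])
        # the relaxation kernel has unit area, so total signal is
        # conserved as tau grows (redistributed into the skirt, not
        # removed); the only loss is the sliver of skirt clipped at the
        # slab edges
        assert totals[400.0] >= totals[0.0] * (1 - 1e-4)
        assert totals[1600.0] >= totals[400.0] * (1 - 1e-4)


class TestAxialProfile:
    def test_uniform_frame_sums(self):
        from framecodec import Frame

        frame = Frame(np.full((12, 20), 2.0))
        cols = axial_profile(frame, "columns")
        rows = axial_profile(frame, "rows")
        assert cols.shape == (20,) and np.allclose(cols, 24.0)
        assert rows.shape == (12,) and np.allclose(rows, 40.0)

    def test_profile_conserves_total_intensity(self, rng):
        from framecodec import Frame

        frame = Frame(rng.random((16, 16)))
        assert axial_profile(frame, "columns").sum() == pytest.approx(
            frame.pixels.sum()
        )

    def test_peak_positions_advance_with_delay(self):
        pump, medium, grid = thin_slab()
        base = 2.0 / pump.speed
        frames = simulate_sequence(
            pump, [base + k * 1000.0 for k in range(4)], medium, grid
        )
        peaks = [int(np.argmax(axial_profile(f, "columns"))) for f in frames]
        assert peaks == sorted(peaks) and len(set(peaks)) == 4
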