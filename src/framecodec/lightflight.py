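"""Synthetic ground truth: a pump-probe Kerr-gate light-in-flight forward
model.

A femtosecond pump pulse traverses a Kerr-sensitive medium (e.g. CS2,
refractive index ~1.63) along x.  Its instantaneous intensity induces a
transient birefringence; between crossed polarizers this acts as an
ultrafast optical shutter for read (probe) pulses propagating along z.  The
gate is not binary: its strength follows the pump intensity profile,
low-pass filtered in time by the orientational relaxation of the medium's
molecules (time constant ``tau_relax``, picosecond scale in CS2).  The
camera sees the z-projection of the gated read light, so each read pulse
delay produces one frame of the pump pulse in flight.

Model assumptions: rigid Gaussian pulses at constant speed ``c/n`` (no
group-velocity dispersion, absorption or pump depletion), a gate
transmission linear in the induced birefringence (small retardance), and
read pulses uniform across the (x, y) aperture.  Fringe coding is applied
downstream by the codec, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erfcx

from .codec import Frame
from .errors import GridTooCoarseError, ValidationError

__all__ = [
    "C_MM_PER_FS",
    "PulseSpec",
    "KerrMediumSpec",
    "GridSpec",
    "pump_intensity",
    "gate_response",
    "frame_signal",
    "simulate_sequence",
    "axial_profile",
]

#: vacuum speed of light in mm/fs
C_MM_PER_FS = 2.99792458e-4

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PulseSpec:
    """A Gaussian laser pulse.

    Parameters
    ----------
    duration_fwhm
        Temporal full width at half maximum (fs).
    t0
        Time at which the pulse center crosses the entry face of the
        medium (fs).
    direction
        Unit propagation vector in the medium frame (x = pump axis,
        z = read/camera axis by convention).
    speed
        Phase-front speed in the medium (mm/fs), i.e. ``c/n``.
    waist
        Transverse 1/e^2 intensity radius at the entry face (mm).
    divergence_angle
        Half-angle (rad) by which the transverse radius grows per unit
        propagation distance; 0 for a collimated beam.
    wavelength
        Center wavelength (nm); carried as metadata.
    energy
        Peak intensity scale (arbitrary units).
    """

    duration_fwhm: float
    t0: float = 0.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    speed: float = C_MM_PER_FS / 1.63
    waist: float = 0.5
    divergence_angle: float = 0.0
    wavelength: float = 800.0
    energy: float = 1.0

    def __post_init__(self) -> None:
        if not (self.duration_fwhm > 0):
            raise ValidationError("duration_fwhm must be > 0")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,) or not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValidationError("direction must be a unit 3-vector")
        object.__setattr__(self, "direction", tuple(float(v) for v in d))
        if not (0 < self.speed <= C_MM_PER_FS + 1e-18):
            raise ValidationError("speed must be in (0, c]")
        if not (self.waist > 0):
            raise ValidationError("waist must be > 0")
        if self.divergence_angle < 0:
            raise ValidationError("divergence_angle must be >= 0")

    @property
    def sigma_t(self) -> float:
        """Temporal Gaussian sigma (fs)."""
        return self.duration_fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class KerrMediumSpec:
    """The Kerr-sensitive medium: a rectangular box of size ``extent``
    (mm per axis) with refractive index ``n_refr`` and orientational
    relaxation time ``tau_relax`` (fs, 0 for an instantaneous gate).

    The default index 1.63 is that of CS2 at 800 nm; the default
    relaxation time 1600 fs is the typical CS2 orientational value.
    """

    n_refr: float = 1.63
    tau_relax: float = 1600.0
    extent: tuple[float, float, float] = (7.0, 7.0, 2.0)

    def __post_init__(self) -> None:
        if self.n_refr < 1:
            raise ValidationError("refractive index must be >= 1")
        if self.tau_relax < 0:
            raise ValidationError("tau_relax must be >= 0")
        if any(e <= 0 for e in self.extent):
            raise ValidationError("medium extent must be positive")

    @property
    def speed(self) -> float:
        """Light speed in the medium (mm/fs)."""
        return C_MM_PER_FS / self.n_refr


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid over the medium; the camera integrates along z onto the
    (x, y) plane, with x mapped to image columns and y to rows."""

    shape: tuple[int, int, int] = (128, 64, 32)
    voxel: tuple[float, float, float] = (7.0 / 128, 7.0 / 64, 2.0 / 32)

    def __post_init__(self) -> None:
        if any(n < 4 for n in self.shape):
            raise ValidationError("grid must have >= 4 voxels per axis")
        if any(v <= 0 for v in self.voxel):
            raise ValidationError("voxel sizes must be positive")

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis, starting at the entry
        face (coordinate 0)."""
        n = self.shape[axis]
        dv = self.voxel[axis]
        return (np.arange(n) + 0.5) * dv

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel))


def _pulse_frame_coords(
    pulse: PulseSpec,
    medium: KerrMediumSpec,
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal coordinate xi (from the entry face, along the pulse
    axis) and transverse distance rho for an (..., 3) array of points.

    The pulse axis passes through the center of the medium box and enters
    at the face it first crosses."""
    d = np.asarray(pulse.direction)
    half = np.asarray(medium.extent) / 2.0
    center = half.copy()
    # entry point: box center pushed back half the box span along -direction
    span_along = float(np.dot(np.abs(d), np.asarray(medium.extent)))
    entry = center - d * (span_along / 2.0)
    rel = np.asarray(points, dtype=float) - entry
    xi = rel @ d
    perp = rel - xi[..., None] * d
    rho = np.linalg.norm(perp, axis=-1)
    return xi, rho


def _transverse_radius(pulse: PulseSpec, xi: np.ndarray) -> np.ndarray:
    """1/e^2 radius at longitudinal position xi (linear growth model)."""
    return pulse.waist + pulse.divergence_angle * np.maximum(xi, 0.0)


def pump_intensity(
    pump: PulseSpec,
    medium: KerrMediumSpec,
    point: Sequence[float] | np.ndarray,
    t: float | np.ndarray,
) -> np.ndarray | float:
    """Pump intensity at a point (mm) and time (fs).

    Separable Gaussian: a longitudinal envelope
    ``exp(-4 ln2 ((xi - v (t - t0)) / (v * duration_fwhm))^2)`` translating
    rigidly at the medium speed, times a transverse Gaussian whose 1/e^2
    radius grows linearly with the divergence angle.  Peak value is
    ``pump.energy``.
    """
    pts = np.asarray(point, dtype=float)
    xi, rho = _pulse_frame_coords(pump, medium, pts)
    t = np.asarray(t, dtype=float)
    v = pump.speed
    center = v * (t - pump.t0)
    longi = np.exp(
        -4.0 * np.log(2.0) * ((xi - center) / (v * pump.duration_fwhm)) ** 2
    )
    w = _transverse_radius(pump, xi)
    trans = np.exp(-2.0 * (rho / w) ** 2)
    out = pump.energy * longi * trans
    return out if out.ndim else float(out)


def _emg_gate(u: np.ndarray, sigma: float, tau: float) -> np.ndarray:
    """Unit-peak Gaussian pulse passed through the relaxation kernel.

    Closed form of ``(1/tau) * int_-inf^t exp(-u'^2/(2 sigma^2))
    * exp(-(t-t')/tau) dt'`` with ``u = t - t_center``: an exponentially
    modified Gaussian, evaluated via the scaled complementary error
    function ``erfcx`` for numerical stability at small ``tau``.
    """
    if tau == 0.0:
        return np.exp(-0.5 * (u / sigma) ** 2)
    u = np.asarray(u, dtype=float)
    z = (sigma / tau - u / sigma) / np.sqrt(2.0)
    pref = np.sqrt(2.0 * np.pi) * sigma / (2.0 * tau)
    out = np.empty_like(u)
    pos = z >= 0
    out[pos] = pref * erfcx(z[pos]) * np.exp(-0.5 * (u[pos] / sigma) ** 2)
    if np.any(~pos):
        # far tail (t well past the pulse): erfcx overflows, so use
        # erfc(z) = 2 - erfc(-z) with the exponents combined analytically;
        # z^2 - u^2/(2 sigma^2) = sigma^2/(2 tau^2) - u/tau
        un = u[~pos]
        tail = 2.0 * np.exp(0.5 * (sigma / tau) ** 2 - un / tau)
        out[~pos] = pref * (
            tail - erfcx(-z[~pos]) * np.exp(-0.5 * (un / sigma) ** 2)
        )
    return out


def gate_response(
    pump: PulseSpec,
    medium: KerrMediumSpec,
    point: Sequence[float] | np.ndarray,
    t: float | np.ndarray,
) -> np.ndarray | float:
    """Kerr-gate strength at a point and time.

    The induced birefringence follows the pump intensity convolved with an
    exponential relaxation kernel of time constant ``tau_relax``:

    ``G(p, t) = (1/tau) * integral_{-inf}^{t} I_pump(p, t') *
    exp(-(t - t') / tau) dt'``

    normalized so that ``tau -> 0`` recovers the instantaneous pump
    intensity.  Because the pump is a rigid Gaussian, the intensity at a
    fixed point is Gaussian in time and the convolution has an
    exponentially-modified-Gaussian closed form, which is what this
    function evaluates (exactly, for any ``tau >= 0``).
    """
    pts = np.asarray(point, dtype=float)
    xi, rho = _pulse_frame_coords(pump, medium, pts)
    t = np.asarray(t, dtype=float)
    v = pump.speed
    sigma = pump.sigma_t
    t_center = pump.t0 + xi / v
    w = _transverse_radius(pump, xi)
    amp = pump.energy * np.exp(-2.0 * (rho / w) ** 2)
    out = amp * _emg_gate(t - t_center, sigma, medium.tau_relax)
    return out if out.ndim else float(out)


def _read_axis_intensity(
    read: PulseSpec, z: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Read-pulse longitudinal envelope on the z axis, shape (nz, nt).

    Read pulses are modeled as uniform across the (x, y) aperture."""
    v = read.speed
    center = v * (t[None, :] - read.t0)
    return read.energy * np.exp(
        -4.0 * np.log(2.0)
        * ((z[:, None] - center) / (v * read.duration_fwhm)) ** 2
    )


def frame_signal(
    pump: PulseSpec,
    read: PulseSpec,
    medium: KerrMediumSpec,
    grid: GridSpec,
    time_oversampling: int = 10,
) -> Frame:
    """One camera frame: the z-projected, time-integrated gated read light.

    ``S(x, y) = integral dz dt  I_read(x, y, z, t) * G(x, y, z, t)``,
    evaluated by midpoint quadrature over the voxel grid and a time grid
    with step ``duration_fwhm / time_oversampling`` (the shorter of the two
    pulse durations).  The pump must propagate along x and the read along z.

    Raises
    ------
    GridTooCoarseError
        If the z grid resolves the read pulse, or the time grid either
        pulse, with fewer than 4 samples.
    """
    if not np.isclose(abs(np.dot(pump.direction, read.direction)), 0.0, atol=1e-9):
        raise ValidationError("read direction must be orthogonal to the pump")
    if tuple(pump.direction) != (1.0, 0.0, 0.0):
        raise ValidationError("pump must propagate along +x")
    if tuple(read.direction) != (0.0, 0.0, 1.0):
        raise ValidationError("read must propagate along +z")
    ext = grid.extent
    if any(abs(e - m) > 1e-9 for e, m in zip(ext, medium.extent)):
        raise ValidationError(
            f"grid extent {ext} does not match medium extent {medium.extent}"
        )
    if time_oversampling < 4:
        raise GridTooCoarseError("need >= 4 time samples across a pulse")

    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    zs = grid.axis_centers(2)
    dz = grid.voxel[2]

    read_len = read.speed * read.duration_fwhm
    if read_len / dz < 4:
        raise GridTooCoarseError(
            f"z voxel {dz:.4g} mm gives {read_len / dz:.1f} samples across "
            "the read pulse; need >= 4"
        )

    dt = min(pump.duration_fwhm, read.duration_fwhm) / time_oversampling
    # read pulse is inside the medium (within +-4 FWHM) during this window
    t_lo = read.t0 - 4.0 * read.duration_fwhm
    t_hi = read.t0 + ext[2] / read.speed + 4.0 * read.duration_fwhm
    nt = int(np.ceil((t_hi - t_lo) / dt))
    ts = t_lo + (np.arange(nt) + 0.5) * dt

    # gate separates into transverse((y,z); x) * EMG(x, t)
    cy, cz = ext[1] / 2.0, ext[2] / 2.0
    sigma = pump.sigma_t
    v = pump.speed
    emg = pump.energy * _emg_gate(
        ts[None, :] - (pump.t0 + xs[:, None] / v), sigma, medium.tau_relax
    )  # (nx, nt)
    i_read = _read_axis_intensity(read, zs, ts)  # (nz, nt)
    gate_by_xz = emg @ i_read.T * dt  # (nx, nz): time-integrated per (x, z)

    rho2 = (ys[:, None] - cy) ** 2 + (zs[None, :] - cz) ** 2  # (ny, nz)
    if pump.divergence_angle == 0.0:
        trans = np.exp(-2.0 * rho2 / pump.waist**2)  # (ny, nz)
        image = (gate_by_xz @ trans.T) * dz  # (nx, ny)
    else:
        w = _transverse_radius(pump, xs)  # (nx,)
        image = np.empty((len(xs), len(ys)))
        for i, wi in enumerate(w):
            trans = np.exp(-2.0 * rho2 / wi**2)
            image[i] = trans @ gate_by_xz[i] * dz
    # camera: x -> columns, y -> rows
    return Frame(
        image.T, pixel_pitch=grid.voxel[0], time_tag=read.t0
    )


def simulate_sequence(
    pump: PulseSpec,
    read_delays: Sequence[float],
    medium: KerrMediumSpec,
    grid: GridSpec,
    read_template: PulseSpec | None = None,
    time_oversampling: int = 10,
) -> list[Frame]:
    """Simulate one frame per read-pulse delay.

    ``read_delays`` (fs, strictly increasing) give each read pulse's entry
    time; the frame rate is the reciprocal of the delay spacing, and the
    maximum usable rate is the reciprocal of the pulse duration (pulses
    back-to-back).  ``read_template`` sets duration/energy of the read
    pulses (default: same duration as the pump, unit energy, along +z).
    With ``tau_relax = 0`` and a rigid pump, successive frames are
    translates of one another.
    """
    delays = [float(d) for d in read_delays]
    if len(delays) < 1:
        raise ValidationError("need at least one read delay")
    if any(b <= a for a, b in zip(delays, delays[1:])):
        raise ValidationError("read delays must be strictly increasing")
    if read_template is None:
        read_template = PulseSpec(
            duration_fwhm=pump.duration_fwhm,
            direction=(0.0, 0.0, 1.0),
            speed=medium.speed,
            waist=pump.waist,
        )
    frames = []
    for i, delay in enumerate(delays):
        read = PulseSpec(
            duration_fwhm=read_template.duration_fwhm,
            t0=delay,
            direction=read_template.direction,
            speed=read_template.speed,
            waist=read_template.waist,
            divergence_angle=read_template.divergence_angle,
            wavelength=read_template.wavelength,
            energy=read_template.energy,
        )
        try:
            frames.append(
                frame_signal(
                    pump, read, medium, grid,
                    time_oversampling=time_oversampling,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"frame {i} (delay {delay} fs): {exc}") from exc
    return frames


def axial_profile(frame: Frame, axis: str = "columns") -> np.ndarray:
    """Sum the frame along rows or columns.

    ``axis="columns"`` sums down each column (the vertical summation used
    to track a pulse propagating along x); the result has length W.
    ``axis="rows"`` sums across each row; length H.
    """
    if axis == "columns":
        return frame.pixels.sum(axis=0)
    if axis == "rows":
        return frame.pixels.sum(axis=1)
    raise ValidationError("axis must be 'rows' or 'columns'")
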