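"""Forward (encoding) model: sinusoidal carrier modulation and composition
of several frames into a single sensor exposure.

A frame is multiplied by a non-negative fringe pattern ``1 + m*cos(2*pi*
(nu_x*x + nu_y*y) + phi)``, which places a conjugate pair of copies of its
spectrum at ``+/-nu`` in reciprocal space.  Summing N frames, each on its
own carrier, yields one multiplexed image; a sensor model then maps the sum
onto full-well electrons, adds optional shot and read noise, and quantizes
to B bits.

Coordinate convention: row-major arrays, origin top-left, 0-based indices;
``x`` is the column index and ``y`` the row index; the fringe phase is
referenced at pixel (0, 0).  Spatial frequencies are in cycles/pixel with
components in [-0.5, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Frame",
    "CarrierCode",
    "CodeBook",
    "SensorModel",
    "MultiplexedExposure",
    "modulate",
    "compose",
]

#: minimum frame side length
MIN_SIDE = 8


@dataclass
class Frame:
    """A nonnegative 2D intensity image with a physical pixel pitch.

    Parameters
    ----------
    pixels
        2D array of nonnegative finite intensities, ``H x W`` with
        ``H, W >= 8``.
    pixel_pitch
        Physical size of one pixel (mm/pixel), ``> 0``.  The default of
        7/1002 mm/pixel corresponds to a 7 mm field of view imaged onto a
        1002-pixel detector.
    time_tag
        Optional acquisition time in fs.
    """

    pixels: np.ndarray
    pixel_pitch: float = 7.0 / 1002.0
    time_tag: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"frame must be 2D, got {self.pixels.ndim}D"
            )
        h, w = self.pixels.shape
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValidationError(
                f"frame must be at least {MIN_SIDE}x{MIN_SIDE}, got {h}x{w}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("frame contains non-finite pixel values")
        if np.any(self.pixels < 0):
            raise ValidationError("frame contains negative intensities")
        if not (self.pixel_pitch > 0):
            raise ValidationError("pixel_pitch must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CarrierCode:
    """Per-frame sinusoidal modulation: carrier frequency, depth, phase.

    ``nu`` is the 2-vector spatial frequency ``(nu_x, nu_y)`` in
    cycles/pixel; its magnitude must lie in ``(0, 0.5]`` (nonzero, at or
    below Nyquist).  ``m`` is the modulation depth (fringe contrast) in
    ``(0, 1]`` and ``phi`` the fringe phase at pixel (0, 0), stored wrapped
    to ``[0, 2*pi)``.
    """

    nu: tuple[float, float]
    m: float = 1.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        nu = (float(self.nu[0]), float(self.nu[1]))
        object.__setattr__(self, "nu", nu)
        mag = float(np.hypot(*nu))
        if not np.isfinite(mag) or mag == 0.0:
            raise ValidationError("carrier frequency must be nonzero")
        if mag > 0.5 + 1e-12:
            raise ValidationError(
                f"|nu| = {mag:.4f} exceeds the Nyquist limit of 0.5 cyc/px"
            )
        if not (0.0 < self.m <= 1.0):
            raise ValidationError(f"modulation depth m={self.m} not in (0, 1]")
        object.__setattr__(self, "phi", float(self.phi) % (2.0 * np.pi))

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.nu))


def _conjugate_aware_separation(
    a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Distance between two carriers taking the mirror at -nu into account.

    For real images each carrier places copies at both +nu and -nu, so the
    relevant spacing between two carriers is the minimum over the conjugate
    pairings.
    """
    ax, ay = a
    bx, by = b
    d_same = np.hypot(ax - bx, ay - by)
    d_conj = np.hypot(ax + bx, ay + by)
    return float(min(d_same, d_conj))


@dataclass
class CodeBook:
    """An ordered, validated set of carriers with the band-pass geometry.

    ``filter_radius`` is the radius of the band-pass window used at decode
    and ``baseband_radius`` the radius of the unmodulated low-frequency
    region around DC.  Validation enforces, for every pair of carriers, a
    conjugate-aware separation of at least ``2 * filter_radius``, that every
    carrier clears the baseband (``|nu| >= baseband_radius + filter_radius``)
    and that its window stays below Nyquist (``|nu| + filter_radius <= 0.5``).
    """

    codes: list[CarrierCode]
    filter_radius: float
    baseband_radius: float

    def __post_init__(self) -> None:
        self.codes = list(self.codes)
        if len(self.codes) < 1:
            raise ValidationError("codebook must contain at least one carrier")
        r = float(self.filter_radius)
        r0 = float(self.baseband_radius)
        if not (r > 0):
            raise ValidationError("filter_radius must be > 0")
        if r0 < 0:
            raise ValidationError("baseband_radius must be >= 0")
        tol = 1e-12
        for i, c in enumerate(self.codes):
            mag = c.magnitude
            if mag + tol < r0 + r:
                raise ValidationError(
                    f"carrier {i} at |nu|={mag:.4f} overlaps the baseband "
                    f"(needs |nu| >= r0 + r = {r0 + r:.4f})"
                )
            if mag + r > 0.5 + tol:
                raise ValidationError(
                    f"carrier {i} band extends beyond Nyquist "
                    f"(|nu| + r = {mag + r:.4f} > 0.5)"
                )
        for i in range(len(self.codes)):
            for j in range(i + 1, len(self.codes)):
                sep = _conjugate_aware_separation(
                    self.codes[i].nu, self.codes[j].nu
                )
                if sep + tol < 2.0 * r:
                    raise ValidationError(
                        f"carriers {i} and {j} are separated by "
                        f"{sep:.4f} < 2r = {2 * r:.4f} cyc/px "
                        "(conjugate-aware)"
                    )

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class SensorModel:
    """Camera model: full-well scaling, optional noise, B-bit quantization.

    The multiplexed sum is scaled so that its maximum maps to ``full_well``
    electrons; Poisson shot noise (if enabled) and Gaussian read noise are
    applied in electrons; the ADC then truncates (floor) to ``2**bit_depth``
    levels with clipping.  ``seed`` makes the noise reproducible.
    """

    bit_depth: int = 16
    full_well: float = 30000.0
    read_noise_sigma: float = 0.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 12, 14, 16):
            raise ValidationError(
                f"bit_depth must be one of 8, 12, 14, 16; got {self.bit_depth}"
            )
        if not (self.full_well > 0):
            raise ValidationError("full_well must be > 0")
        if self.read_noise_sigma < 0:
            raise ValidationError("read_noise_sigma must be >= 0")

    @property
    def max_dn(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class MultiplexedExposure:
    """The single coded camera image plus the codebook and sensor that
    produced it.

    ``gain`` records digital numbers per unit of input frame intensity
    (before noise), so decoded frames can be compared quantitatively with
    the inputs.
    """

    pixels: np.ndarray
    codebook: CodeBook
    sensor: SensorModel
    gain: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("exposure must be 2D")
        if self.pixels.max(initial=0) > self.sensor.max_dn:
            raise ValidationError(
                f"exposure exceeds {self.sensor.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def carrier_field(
    shape: tuple[int, int], code: CarrierCode
) -> np.ndarray:
    """The fringe pattern ``1 + m*cos(2*pi*(nu_x*x + nu_y*y) + phi)`` on an
    ``H x W`` grid (x = column index, y = row index)."""
    h, w = shape
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    nux, nuy = code.nu
    arg = 2.0 * np.pi * (nux * x + nuy * y) + code.phi
    return 1.0 + code.m * np.cos(arg)


def modulate(frame: Frame, code: CarrierCode) -> Frame:
    """Superimpose a sinusoidal carrier onto a frame.

    Returns a new frame whose pixel (y, x) equals
    ``frame(y, x) * (1 + m*cos(2*pi*(nu_x*x + nu_y*y) + phi))``.  In
    reciprocal space this places a conjugate pair of attenuated copies of
    the frame spectrum at ``+/-nu``, each scaled by ``m/2``.
    """
    fringes = carrier_field(frame.shape, code)
    out = frame.pixels * fringes
    # Guard against tiny negative round-off from cos at depth m = 1.
    np.clip(out, 0.0, None, out=out)
    return Frame(out, pixel_pitch=frame.pixel_pitch, time_tag=frame.time_tag)


def multiplex_sum(frames: Sequence[Frame], codebook: CodeBook) -> np.ndarray:
    """The noiseless, unquantized multiplexed image: the sum of every
    frame modulated with its carrier (codebook order).  This is the linear
    part of :func:`compose`, before the sensor model."""
    frames = list(frames)
    if len(frames) == 0:
        raise ValidationError("cannot compose an empty frame list")
    if len(frames) != len(codebook.codes):
        raise ValidationError(
            f"{len(frames)} frames but {len(codebook.codes)} carriers"
        )
    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape:
            raise ValidationError(
                f"frame {i} has shape {f.shape}, expected {shape}"
            )
    total = np.zeros(shape, dtype=float)
    for f, code in zip(frames, codebook.codes):
        total += modulate(f, code).pixels
    return total


def compose(
    frames: Sequence[Frame],
    codebook: CodeBook,
    sensor: SensorModel | None = None,
) -> MultiplexedExposure:
    """Encode a frame sequence into one multiplexed sensor exposure.

    Each frame is modulated with its carrier from the codebook (order is
    preserved) and the results are summed.  The sum is scaled so its maximum
    fills the sensor's full well, noise is applied in electrons if enabled,
    and the ADC floors to ``bit_depth`` bits with clipping, so a noise-free
    exposure always peaks at ``2**B - 1``.
    """
    if sensor is None:
        sensor = SensorModel()
    total = multiplex_sum(frames, codebook)
    shape = total.shape
    peak = total.max()
    if peak <= 0:
        raise ValidationError("composed exposure is identically zero")
    electrons = total * (sensor.full_well / peak)

    rng = np.random.default_rng(sensor.seed)
    if sensor.shot_noise:
        electrons = rng.poisson(electrons).astype(float)
    if sensor.read_noise_sigma > 0:
        electrons = electrons + rng.normal(
            0.0, sensor.read_noise_sigma, size=shape
        )

    dn = np.floor(electrons * (sensor.max_dn / sensor.full_well))
    np.clip(dn, 0, sensor.max_dn, out=dn)
    dtype = np.uint8 if sensor.bit_depth == 8 else np.uint16
    gain = sensor.max_dn / peak  # DN per unit input intensity
    return MultiplexedExposure(
        pixels=dn.astype(dtype), codebook=codebook, sensor=sensor, gain=gain
    )
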