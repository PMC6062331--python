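"""Reciprocal-space codebook planning and capacity arithmetic.

Carriers are placed on concentric rings in the annulus between the
baseband (radius ``r0``) plus one filter radius and the optical cutoff
minus one filter radius, with angles uniformly spaced over ``[0, pi)`` per
ring — conjugate symmetry of real images makes the lower half-plane
redundant and halves the usable angular range.  Separation checks are
conjugate-aware: each carrier's mirror at ``-nu`` is included, since both
sidebands of every frame occupy the spectrum.

The ring construction is deterministic and reproducible; it lower-bounds
the true geometric packing optimum, which is sufficient for the small
frame counts (N <= 16) this codec targets.  Maximal dispersion of the
carriers lets the decoder use large band-pass windows, and the window size
in turn sets the spatial resolution of the decoded frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .codec import CarrierCode, CodeBook
from .errors import InfeasiblePackingError, ValidationError

__all__ = [
    "PackingSpec",
    "plan_codebook",
    "capacity",
    "effective_bit_depth",
    "lpmm_from_cycles",
]

NYQUIST = 0.5


@dataclass(frozen=True)
class PackingSpec:
    """Geometry of a carrier-packing problem.

    Parameters
    ----------
    n_frames
        Number of carriers to place.
    filter_radius
        Band-pass radius ``r`` (cycles/pixel) planned for decoding.
    baseband_radius
        Radius ``r0`` of the unmodulated content around DC.
    otf_cutoff
        Optical resolution limit of the imaging system (cycles/pixel);
        carriers plus their windows must fit inside it.  At most the
        Nyquist frequency 0.5.
    min_separation
        Required conjugate-aware spacing between carriers; defaults to
        ``2 * filter_radius`` (adjacent windows just touching).
    guard
        Multiplier applied to ``min_separation`` during planning (default
        1.1) so finite window skirts retain a guard band.
    """

    n_frames: int
    filter_radius: float
    baseband_radius: float
    otf_cutoff: float = 0.45
    min_separation: Optional[float] = None
    guard: float = 1.1

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        r, r0 = self.filter_radius, self.baseband_radius
        if not (r > 0):
            raise ValidationError("filter_radius must be > 0")
        if r0 < 0:
            raise ValidationError("baseband_radius must be >= 0")
        if not (self.otf_cutoff <= NYQUIST + 1e-12):
            raise ValidationError("otf_cutoff cannot exceed Nyquist (0.5)")
        if r0 + 2 * r > self.otf_cutoff + 1e-12:
            raise ValidationError(
                f"r0 + 2r = {r0 + 2 * r:.4f} exceeds otf_cutoff "
                f"{self.otf_cutoff:.4f}: no room for any carrier"
            )
        if self.guard < 1.0:
            raise ValidationError("guard factor must be >= 1")

    @property
    def separation(self) -> float:
        """Effective planning separation (min_separation times guard)."""
        base = (
            2.0 * self.filter_radius
            if self.min_separation is None
            else self.min_separation
        )
        return base * self.guard

    @property
    def r_min(self) -> float:
        return self.baseband_radius + self.filter_radius

    @property
    def r_max(self) -> float:
        return self.otf_cutoff - self.filter_radius


def _ring_capacity(rho: float, sep: float) -> int:
    """Carriers that fit on one ring of radius rho at chord spacing >= sep.

    Angles are uniform over [0, pi); together with the conjugate images the
    angular pitch of the combined point set is pi/k, so the tightest chord
    is 2*rho*sin(pi/(2k)).
    """
    if rho <= 0:
        return 0
    if sep >= 2.0 * rho:
        return 1
    k = math.pi / (2.0 * math.asin(sep / (2.0 * rho)))
    return max(1, int(math.floor(k + 1e-9)))


def _ring_layout(spec: PackingSpec, n_rings: int) -> list[float]:
    if n_rings == 1:
        return [(spec.r_min + spec.r_max) / 2.0]
    return list(np.linspace(spec.r_min, spec.r_max, n_rings))


def _max_rings(spec: PackingSpec) -> int:
    span = spec.r_max - spec.r_min
    if span < 0:
        return 0
    if span == 0:
        return 1
    return 1 + int(math.floor(span / spec.separation + 1e-9))


def capacity(spec: PackingSpec) -> int:
    """Maximum number of carriers the ring construction can place.

    This is a constructive lower bound on the geometric optimum: the best
    total over ring counts of per-ring capacities, with rings spaced at
    least one separation apart radially.
    """
    best = 0
    for n_rings in range(1, _max_rings(spec) + 1):
        radii = _ring_layout(spec, n_rings)
        best = max(best, sum(_ring_capacity(rho, spec.separation) for rho in radii))
    return best


def plan_codebook(
    spec: PackingSpec, depth: float = 1.0, phase: float = 0.0
) -> CodeBook:
    """Deterministically place ``n_frames`` carriers and return a validated
    codebook.

    The smallest ring count whose total capacity covers ``n_frames`` is
    used; carriers are distributed over rings proportionally to ring
    capacity (largest remainder) and spaced uniformly in angle over
    ``[0, pi)``, with a small angular stagger between rings.  All carriers
    share the given modulation depth and phase.

    Raises
    ------
    InfeasiblePackingError
        If the construction cannot place ``n_frames`` carriers; the message
        names the binding constraint.
    """
    cap = capacity(spec)
    if cap < spec.n_frames:
        raise InfeasiblePackingError(
            f"requested {spec.n_frames} carriers but the annulus "
            f"[{spec.r_min:.4f}, {spec.r_max:.4f}] cyc/px at separation "
            f"{spec.separation:.4f} admits only {cap}; widen the annulus "
            "(smaller filter_radius or baseband_radius, larger otf_cutoff) "
            "or reduce the separation"
        )

    chosen_radii: list[float] | None = None
    chosen_caps: list[int] | None = None
    for n_rings in range(1, _max_rings(spec) + 1):
        radii = _ring_layout(spec, n_rings)
        caps = [_ring_capacity(rho, spec.separation) for rho in radii]
        if sum(caps) >= spec.n_frames:
            chosen_radii, chosen_caps = radii, caps
            break
    assert chosen_radii is not None and chosen_caps is not None

    # largest-remainder apportionment of carriers to rings
    total_cap = sum(chosen_caps)
    quotas = [spec.n_frames * c / total_cap for c in chosen_caps]
    counts = [min(int(math.floor(q)), c) for q, c in zip(quotas, chosen_caps)]
    remainder = spec.n_frames - sum(counts)
    order = sorted(
        range(len(quotas)), key=lambda i: quotas[i] - math.floor(quotas[i]),
        reverse=True,
    )
    for i in order:
        if remainder == 0:
            break
        if counts[i] < chosen_caps[i]:
            counts[i] += 1
            remainder -= 1
    # fill any slack left by the quota caps
    for i in range(len(counts)):
        while remainder > 0 and counts[i] < chosen_caps[i]:
            counts[i] += 1
            remainder -= 1
    assert remainder == 0

    codes: list[CarrierCode] = []
    for ring_idx, (rho, count) in enumerate(zip(chosen_radii, counts)):
        if count == 0:
            continue
        stagger = ring_idx * math.pi / (2.0 * count * len(chosen_radii))
        for k in range(count):
            theta = k * math.pi / count + stagger
            nu = (rho * math.cos(theta), rho * math.sin(theta))
            codes.append(CarrierCode(nu=nu, m=depth, phi=phase))

    return CodeBook(
        codes=codes,
        filter_radius=spec.filter_radius,
        baseband_radius=spec.baseband_radius,
    )


def snap_codebook(codebook: CodeBook, shape: tuple[int, int]) -> CodeBook:
    """Snap every carrier onto the DFT grid of an ``H x W`` detector.

    A carrier with a non-integer number of fringe cycles across the image
    leaks spectral energy from the image borders into every band-pass
    window (a wraparound artifact of the discrete transform).  When the
    sensor size is known in advance — always the case for synthetic
    studies, and standard calibration practice for real systems — rounding
    each frequency component to the nearest DFT bin makes the fringes
    periodic on the detector and eliminates that leakage entirely.

    Each component moves by at most half a bin (``1/(2N)`` cycles/pixel);
    the snapped codebook is re-validated, so a plan without enough guard
    band for the shift is rejected rather than silently degraded.
    """
    h, w = shape
    snapped = [
        CarrierCode(
            nu=(round(c.nu[0] * w) / w, round(c.nu[1] * h) / h),
            m=c.m,
            phi=c.phi,
        )
        for c in codebook.codes
    ]
    return CodeBook(
        codes=snapped,
        filter_radius=codebook.filter_radius,
        baseband_radius=codebook.baseband_radius,
    )


def effective_bit_depth(bit_depth: int, n_frames: int) -> float:
    """Per-frame dynamic range when N overlapping frames share one sensor.

    N spatially overlapping image copies share the full-well capacity, so
    each retains ``B - log2(N)`` bits: e.g. eight copies on a 16-bit sensor
    keep 13 bits apiece.
    """
    if bit_depth < 1:
        raise ValidationError("bit_depth must be >= 1")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if n_frames > 2 ** bit_depth:
        raise ValidationError(
            f"{n_frames} frames exceed the {2 ** bit_depth} quantization "
            f"levels of a {bit_depth}-bit sensor"
        )
    return bit_depth - math.log2(n_frames)


def lpmm_from_cycles(nu_mag: float, pixel_pitch: float) -> float:
    """Convert cycles/pixel to line pairs per millimetre.

    ``pixel_pitch`` is in mm/pixel; one cycle of a sinusoidal fringe is one
    line pair.
    """
    if not (pixel_pitch > 0):
        raise ValidationError("pixel_pitch must be > 0")
    return nu_mag / pixel_pitch
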