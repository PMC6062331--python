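"""Synthetic codec test patterns.

The light-in-flight simulator (:mod:`framecodec.lightflight`) is the
physically motivated ground-truth source; this module provides abstract
band-limited test patterns for quantitative codec validation, where the
content must sit strictly inside a band-pass window of known radius.
"""

from __future__ import annotations

import numpy as np

from .codec import Frame
from .errors import ValidationError

__all__ = ["bandlimited_random_frames", "two_point_frame"]


def bandlimited_random_frames(
    n: int,
    shape: tuple[int, int],
    cutoff: float,
    rng: np.random.Generator,
    offset: float = 1.1,
    pixel_pitch: float = 7.0 / 1002.0,
) -> list[Frame]:
    """Random smooth frames strictly band-limited below ``cutoff``.

    Each frame is synthesized in the Fourier domain — white complex noise
    masked to ``|f| < cutoff`` cycles/pixel, inverse transformed, real part
    taken — so it is periodic on its grid and contains no spectral energy
    at or above the cutoff.  The result is normalized to unit peak
    deviation and raised by ``offset`` (> 1) to keep intensities positive.
    """
    if not (0 < cutoff <= 0.5):
        raise ValidationError("cutoff must be in (0, 0.5]")
    if offset <= 1.0:
        raise ValidationError("offset must exceed 1 to keep intensities >= 0")
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    mask = np.hypot(fx, fy) < cutoff
    frames = []
    for _ in range(n):
        spec = (rng.normal(size=shape) + 1j * rng.normal(size=shape)) * mask
        img = np.fft.ifft2(spec).real
        img /= np.abs(img).max()
        frames.append(Frame(img + offset, pixel_pitch=pixel_pitch))
    return frames


def two_point_frame(
    shape: tuple[int, int],
    separation: float,
    sigma: float = 0.7,
    pixel_pitch: float = 7.0 / 1002.0,
) -> Frame:
    """Two narrow Gaussian spots ``separation`` pixels apart along x,
    centered in the frame — the classic two-point resolution target."""
    h, w = shape
    y = np.arange(h)[:, None] - h / 2.0
    x = np.arange(w)[None, :] - w / 2.0
    blob = lambda dx: np.exp(-((x - dx) ** 2 + y**2) / (2.0 * sigma**2))
    return Frame(
        blob(-separation / 2.0) + blob(separation / 2.0),
        pixel_pitch=pixel_pitch,
    )
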