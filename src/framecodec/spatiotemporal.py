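"""Post-decode analysis: temporal interpolation of frame sequences and
quantitative fidelity / crosstalk metrics.

Because both pump and read pulses propagate during each exposure, a frame
is not an instantaneous snapshot; with several frames of a single event,
interpolation between them estimates intermediate states of the evolving
wave front.  Interpolation here is per-pixel along time in the intensity
domain (motion-compensated interpolation is deliberately out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d

from .codec import Frame
from .errors import ValidationError

__all__ = [
    "FrameSequence",
    "reconstruct_wavefront",
    "fidelity",
    "crosstalk_matrix",
]

DEFAULT_BORDER = 5


@dataclass
class FrameSequence:
    """An ordered, uniformly shaped stack of frames with strictly
    increasing acquisition times (fs)."""

    frames: list[Frame]
    times: list[float]

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        self.times = [float(t) for t in self.times]
        if len(self.frames) != len(self.times):
            raise ValidationError("frames and times must have equal length")
        if len(self.frames) < 1:
            raise ValidationError("a sequence needs at least one frame")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("times must be strictly increasing")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValidationError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        """(T, H, W) array of pixel data."""
        return np.stack([f.pixels for f in self.frames])


def reconstruct_wavefront(
    seq: FrameSequence,
    query_times: Sequence[float],
    mode: Literal["linear", "cubic"] = "linear",
) -> FrameSequence:
    """Interpolate the sequence per-pixel along time at the query times.

    Linear mode returns convex combinations of the two bracketing frames
    (so every output pixel is bounded by its neighbors' min/max and a query
    at a sample time reproduces that frame exactly); cubic mode uses a
    monotonicity-limited piecewise cubic (PCHIP), which is also exact at
    the samples and avoids overshoot ringing.  Extrapolation is refused.
    """
    if len(seq) < 2:
        raise ValidationError("interpolation needs at least two frames")
    q = np.asarray(query_times, dtype=float)
    if q.ndim != 1 or len(q) == 0:
        raise ValidationError("query_times must be a non-empty 1D sequence")
    t = np.asarray(seq.times)
    if q.min() < t[0] or q.max() > t[-1]:
        raise ValidationError(
            f"query times must lie within [{t[0]}, {t[-1]}] fs; "
            "extrapolation is not supported"
        )
    data = seq.stack()
    if mode == "linear":
        interp = interp1d(t, data, axis=0, kind="linear", assume_sorted=True)
    elif mode == "cubic":
        if len(t) < 3:
            raise ValidationError("cubic mode needs at least three frames")
        interp = PchipInterpolator(t, data, axis=0)
    else:
        raise ValidationError("mode must be 'linear' or 'cubic'")
    out = interp(q)
    # exact reproduction at sample times (bypasses interpolator round-off)
    for k, tq in enumerate(q):
        hit = np.nonzero(t == tq)[0]
        if hit.size:
            out[k] = data[hit[0]]
    pitch = seq.frames[0].pixel_pitch
    frames = [
        Frame(np.clip(o, 0.0, None), pixel_pitch=pitch, time_tag=tq)
        for o, tq in zip(out, q)
    ]
    return FrameSequence(frames=frames, times=list(q))


def _region(pixels: np.ndarray, border: int) -> np.ndarray:
    if border > 0:
        return pixels[border:-border, border:-border]
    return pixels


def fidelity(
    decoded: Frame | np.ndarray,
    truth: Frame | np.ndarray,
    border: int = DEFAULT_BORDER,
) -> dict[str, float]:
    """Normalized RMS error and Pearson correlation of a decoded frame
    against its ground truth.

    ``nrmse = RMS(decoded - truth) / (max(truth) - min(truth))`` over the
    border-excluded region (default 5-pixel border, which absorbs the
    circular-convolution wraparound of the decoder).  Requires a
    non-constant truth.
    """
    d = decoded.pixels if isinstance(decoded, Frame) else np.asarray(decoded, float)
    t = truth.pixels if isinstance(truth, Frame) else np.asarray(truth, float)
    if d.shape != t.shape:
        raise ValidationError(f"shape mismatch: {d.shape} vs {t.shape}")
    d = _region(d, border)
    t = _region(t, border)
    rng = float(t.max() - t.min())
    if rng == 0.0:
        raise ValidationError(
            "nrmse undefined for a constant (e.g. all-zero) truth frame"
        )
    nrmse = float(np.sqrt(np.mean((d - t) ** 2)) / rng)
    dc = d - d.mean()
    tc = t - t.mean()
    denom = float(np.sqrt((dc**2).sum() * (tc**2).sum()))
    pearson = float((dc * tc).sum() / denom) if denom > 0 else float("nan")
    return {"nrmse": nrmse, "pearson_r": pearson}


def crosstalk_matrix(
    truth_frames: Sequence[Frame | np.ndarray],
    decoded_frames: Sequence[Frame | np.ndarray],
    border: int = DEFAULT_BORDER,
) -> np.ndarray:
    """N x N channel-mixing matrix between truth and decoded frames.

    Each decoded frame is decomposed on the basis of the truth frames by
    least squares: entry (i, j) is the coefficient of truth frame i in the
    decomposition of decoded frame j.  For a perfect decode the matrix is
    the identity; off-diagonal entries of column j measure how much of the
    *other* channels leaked into decoded frame j.  A blank (all-zero) truth
    frame is handled through the pseudo-inverse: its row is zero, and its
    decoded column exposes pure leakage.
    """
    if len(truth_frames) != len(decoded_frames):
        raise ValidationError("truth and decoded counts differ")
    t_vecs = []
    d_vecs = []
    shape = None
    for tf, df in zip(truth_frames, decoded_frames):
        tp = tf.pixels if isinstance(tf, Frame) else np.asarray(tf, float)
        dp = df.pixels if isinstance(df, Frame) else np.asarray(df, float)
        if shape is None:
            shape = tp.shape
        if tp.shape != shape or dp.shape != shape:
            raise ValidationError("all frames must share one shape")
        t_vecs.append(_region(tp, border).ravel())
        d_vecs.append(_region(dp, border).ravel())
    basis = np.stack(t_vecs, axis=1)  # (npix, N)
    targets = np.stack(d_vecs, axis=1)  # (npix, N)
    return np.linalg.pinv(basis) @ targets
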