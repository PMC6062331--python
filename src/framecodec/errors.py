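"""Exception hierarchy.

All package errors derive from :class:`FrameCodecError` so callers (and the
CLI) can distinguish validation problems (exit code 2) from infeasible
codebook planning (exit code 3).
"""


class FrameCodecError(Exception):
    """Base class for all framecodec errors."""


class ValidationError(FrameCodecError, ValueError):
    """An input violated a documented invariant or precondition."""


class InfeasiblePackingError(FrameCodecError):
    """The requested number of carriers cannot be placed under the
    separation / Nyquist / baseband constraints.  The message names the
    binding constraint."""


class CarriersNotFoundError(FrameCodecError):
    """Fewer carrier peaks than expected rise above the detection
    threshold in the spectrum."""


class GridTooCoarseError(ValidationError):
    """A quadrature grid resolves a pulse with fewer than the minimum
    number of samples."""
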