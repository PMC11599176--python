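"""Exception hierarchy.

Every error contract in the package raises one of these, so callers can
distinguish e.g. a degenerate amplitude series (MI undefined) from a
degenerate surrogate distribution (z undefined) without string matching.
"""


class GaitPacError(Exception):
    """Base class for all package errors."""


class NyquistError(GaitPacError, ValueError):
    """A requested frequency or band violates the Nyquist limit."""


class CoverageError(GaitPacError, ValueError):
    """The recording does not cover the requested gait-relative span."""


class MissingChannelError(GaitPacError, KeyError):
    """A required channel label is absent from the recording."""

    def __init__(self, channel: str):
        super().__init__(channel)
        self.channel = channel

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"required channel {self.channel!r} not present"


class DegenerateAmplitudeError(GaitPacError, ValueError):
    """Amplitude series is identically zero: the phase-amplitude
    distribution (and hence MI) is undefined."""


class DegenerateSurrogateError(GaitPacError, ValueError):
    """The surrogate MI distribution has zero spread: the z-score is
    undefined (e.g. constant amplitude envelope)."""


class IcaConvergenceError(GaitPacError, RuntimeError):
    """ICA decomposition failed to converge; caller may fall back to the
    deterministic notch method."""


class SingularFitError(GaitPacError, RuntimeError):
    """Mixed-model fit is singular or did not converge."""


class FileFormatError(GaitPacError, ValueError):
    """A recording / table file could not be parsed."""
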