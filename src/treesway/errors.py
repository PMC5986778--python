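"""Exception hierarchy.

Every stage of the analysis pipeline raises a subclass of
:class:`TreeswayError`, so callers (and the CLI) can attribute a failure
to a pipeline stage without parsing messages.
"""


class TreeswayError(Exception):
    """Base class for all errors raised by this package."""

    stage: str = "treesway"


class OverdampedError(TreeswayError, ValueError):
    """Decay constant >= natural frequency: motion is not oscillatory."""

    stage = "model"


class ParameterError(TreeswayError, ValueError):
    """Invalid model or configuration parameter."""

    stage = "model"


class SamplingError(TreeswayError, ValueError):
    """Sample rate or time base inadequate for the requested motion."""

    stage = "simulate"


class ExtremaError(TreeswayError, ValueError):
    """Extremum detection failed (no qualifying extrema, constant signal...)."""

    stage = "extrema"


class CoincidenceError(TreeswayError, ValueError):
    """No zero crossing in the extrema time-difference series.

    Raised when the two damped frequencies are too close (or equal), or the
    record too short, for the lateral drift between the two principal
    oscillations to accumulate into a detectable coincidence time t1.
    """

    stage = "t1"


class GeometryError(TreeswayError, ValueError):
    """Degenerate geometry in the rectangle-diagonal construction."""

    stage = "alpha"


class FitError(TreeswayError, RuntimeError):
    """Nonlinear least-squares fit failed to converge.

    Carries the last iterate and its residual for post-mortem inspection.
    """

    stage = "fit"

    def __init__(self, message, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


class TrackFormatError(TreeswayError, ValueError):
    """Malformed or non-uniformly sampled marker track file."""

    stage = "io"
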