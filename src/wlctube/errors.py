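"""Exception types shared across the package."""


class WlctubeError(Exception):
    """Base class for all package-specific errors."""


class ValidityError(WlctubeError, ValueError):
    """The channel is too wide for the deflection picture.

    The modified deflection length is defined only while
    ``(Hh/Lp)^(-2/3) + (Hw/Lp)^(-2/3) > theta / A_box``; outside that
    domain the logarithm in the deflection formula has a non-positive
    argument and the chain no longer behaves as a sequence of
    wall-deflected segments.
    """


class ConfigurationError(WlctubeError, ValueError):
    """A solver or simulation was configured inconsistently."""


class ConvergenceError(WlctubeError, RuntimeError):
    """An iterative computation failed to reach its tolerance."""

    def __init__(self, message: str, last_estimates=None):
        super().__init__(message)
        self.last_estimates = last_estimates


class StepRejectionError(WlctubeError, RuntimeError):
    """A Brownian-dynamics step could not be projected back onto the
    rod-length constraint manifold; reduce the time step."""


class AnalysisError(WlctubeError, ValueError):
    """Trajectory analysis could not produce a valid estimate."""


class TrajectoryParseError(WlctubeError, ValueError):
    """A trajectory file is malformed."""

    def __init__(self, message: str, path=None, line=None):
        loc = f"{path}:{line}: " if path is not None and line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line
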