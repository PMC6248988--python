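"""Exception hierarchy for digikit.

Every error raised on a user-facing path derives from :class:`DigikitError`
so the CLI can map failures to distinct exit codes.
"""


class DigikitError(Exception):
    """Base class for all digikit errors."""

    exit_code = 4


class RigidityError(DigikitError):
    """A matrix claimed to be a rigid transform is not orthonormal/det +1."""

    exit_code = 4


class FormatError(DigikitError):
    """A file does not conform to its declared format (carries line info)."""

    exit_code = 5

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        super().__init__(prefix + message)


class DegenerateCalibrationError(DigikitError):
    """Calibration poses lack the rotational diversity to identify the tip."""


class ConvergenceError(DigikitError):
    """The constrained optimizer failed to converge."""

    def __init__(self, message: str, objective: float | None = None):
        self.objective = objective
        if objective is not None:
            message = f"{message} (final objective {objective:.6g})"
        super().__init__(message)


class InsufficientDataError(DigikitError):
    """Too few pose samples inside a required time window."""


class MissingTrackerError(DigikitError):
    """No tracker pose close enough in time to a measurement."""


class UnknownDeviceError(DigikitError):
    """Device id absent from the pose stream."""


class UnknownLabelError(DigikitError):
    """Label absent from the montage / session."""


class DegeneracyError(DigikitError):
    """Point configuration too degenerate for a unique rigid alignment."""
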