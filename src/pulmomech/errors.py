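"""Exception hierarchy.

``ConfigurationError``/``InvalidSpecError`` map to CLI exit code 2,
``AnalysisError`` and its subclasses to exit code 3.
"""


class PulmomechError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PulmomechError, ValueError):
    """A synthetic-data or maneuver specification violates its invariants."""


class ConfigurationError(PulmomechError):
    """Missing or inconsistent configuration/metadata (e.g. cannula coefficients)."""


class UsageError(PulmomechError):
    """Operands do not belong together (e.g. mismatched compartment labels)."""


class AnalysisError(PulmomechError):
    """An analysis stage could not produce a result from the given data."""


class InsufficientOcclusionError(AnalysisError):
    """Occlusion window shorter than the required read-out interval."""


class CalibrationError(AnalysisError):
    """Deflection calibration failed (no detectable contact)."""


class DegenerateExcitationError(AnalysisError):
    """Oscillation amplitude below the noise floor at every stimulus frequency."""


class EmptyTissueError(AnalysisError):
    """Image contains no tissue after binarization."""


class UndefinedLmError(AnalysisError):
    """No probe-line intercepts: the mean linear intercept is undefined."""
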