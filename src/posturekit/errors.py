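"""Exception hierarchy for posturekit.

Every error raised by the toolkit derives from :class:`PostureKitError` so
callers (and the CLI) can catch toolkit failures without masking bugs.
"""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class FormatError(PostureKitError):
    """A file does not conform to the documented schema (header, columns)."""


class IntegrityError(PostureKitError):
    """A file parses but its content is internally inconsistent
    (non-monotonic time, declared vs. inferred sampling-rate mismatch,
    too few samples)."""


class ResolutionError(PostureKitError):
    """A manifest references a trial file that cannot be found."""


class RangeError(PostureKitError):
    """A clinical outcome value lies outside its defined scale."""


class LoadError(PostureKitError):
    """Total vertical force at a retained sample is below the minimum-load
    threshold, so the COP is numerically unreliable there."""


class SensorError(PostureKitError):
    """A load-cell channel reports a negative force beyond tolerance."""


class GeometryError(PostureKitError):
    """A COP sample lies outside the sensor rectangle where the inverse
    force model is undefined."""


class ParameterError(PostureKitError):
    """An operation received an out-of-range parameter (e.g. a low-pass
    cutoff at or above Nyquist)."""


class ContractError(PostureKitError):
    """An operation's precondition on its input object is violated
    (e.g. directional ranges requested on an uncentered trajectory)."""


class CalibrationError(PostureKitError):
    """A game calibration cannot be built (missing direction, zero limit)."""


class StateError(PostureKitError):
    """An operation was applied to an object in the wrong state
    (e.g. stepping a finished game)."""


class ConfigError(PostureKitError):
    """A run configuration contains unknown or invalid keys."""
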