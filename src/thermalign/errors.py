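"""Exception hierarchy.

The CLI maps :class:`ConfigError` to exit code 2 and data-level errors
(:class:`FormatError`, :class:`ValidationError`, :class:`DataError`,
:class:`ModelIOError`) to exit code 3.
"""


class ThermalignError(Exception):
    """Base class for all package errors."""


class FormatError(ThermalignError):
    """A file's content does not match its declared format."""


class ValidationError(ThermalignError):
    """An in-memory object violates an invariant."""


class ConfigError(ThermalignError):
    """Invalid configuration value or unknown configuration key."""


class DataError(ThermalignError):
    """A dataset-level problem (missing file, bad record, schema mismatch)."""


class ModelIOError(ThermalignError):
    """Model archive unreadable, truncated, or of an incompatible version."""


class DegenerateShapeError(ValidationError):
    """A shape has no spatial extent (all points coincident)."""
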