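"""Exception hierarchy.

All package-specific failures derive from :class:`SleepHMMError` so callers
can catch one base class; the subclasses mirror the distinct error contracts
(input validation, sequence alignment, channel configuration, file format,
model serialization).
"""


class SleepHMMError(Exception):
    """Base class for all package errors."""


class ValidationError(SleepHMMError, ValueError):
    """Invalid input values or inconsistent model state."""


class AlignmentError(SleepHMMError, ValueError):
    """Sequences that must share a common grid do not."""


class ConfigurationError(SleepHMMError, KeyError):
    """A requested channel or configuration key is absent."""


class FormatError(SleepHMMError, ValueError):
    """A file does not conform to its expected on-disk format."""


class SerializationError(SleepHMMError, ValueError):
    """A model archive is truncated, corrupted, or version-incompatible."""
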