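"""Exception hierarchy.

Every error raised by this package derives from :class:`RegulonPulseError`,
so callers (and the CLI) can catch one type. The subclasses separate the
three failure modes the pipeline distinguishes: malformed input files,
invalid configuration/arguments, and computations that cannot proceed on
otherwise well-formed data.
"""


class RegulonPulseError(Exception):
    """Base class for all package errors."""


class FormatError(RegulonPulseError):
    """A file violates its expected table/graph dialect."""


class ConfigurationError(RegulonPulseError):
    """A configuration object or argument combination is invalid."""


class UsageError(RegulonPulseError):
    """An operation was called with arguments outside its contract."""


class ComputationError(RegulonPulseError):
    """Valid inputs on which the requested computation is undefined."""
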