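"""Exception hierarchy.

All package errors derive from :class:`PlantOODError`.  Errors that a user
can fix by changing inputs or flags (bad parameters, malformed files,
protocol violations) additionally derive from :class:`ValidationError`,
which the CLI maps to exit code 2; anything else exits 1.
"""


class PlantOODError(Exception):
    """Base class for all plantood errors."""


class ValidationError(PlantOODError):
    """User-correctable problem: bad input, parameter or configuration."""


class ParameterError(ValidationError, ValueError):
    """An argument is out of its valid range (e.g. temperature <= 0)."""


class InputError(ValidationError, ValueError):
    """Input data violates a precondition (non-finite, empty, zero rows)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but degenerate for the requested op."""


class ParseError(InputError):
    """A file could not be parsed; message carries path and line number."""


class ProtocolError(ValidationError):
    """Open-set protocol violation: overlapping splits, mixed feature
    spaces, training banks containing unknown-class rows."""


class AlignmentError(ValidationError):
    """Sample identifiers disagree between containers being combined."""


class ConfigurationError(ValidationError):
    """A mode requires an input that was not supplied."""


class GenerationError(ValidationError):
    """The synthetic generator cannot satisfy the requested geometry."""
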