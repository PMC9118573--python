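"""Exception hierarchy.

Everything raised on bad user input derives from :class:`MonofilmError`,
so callers (and the CLI, which maps these to exit code 2) can catch one type.
"""


class MonofilmError(Exception):
    """Base class for all monofilm errors."""


class ValidationError(MonofilmError):
    """Input data violates a structural invariant (too few points, bad ordering...)."""


class FormatError(ValidationError):
    """A file does not conform to the expected layout (missing column, bad header)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the offending row index in the message."""


class ParameterError(MonofilmError):
    """An analysis parameter is out of its allowed range (even window, degree >= window...)."""


class RangeError(ValidationError):
    """A requested abscissa lies outside the achievable range of the data."""


class AlignmentError(ValidationError):
    """Two resampled curves do not share a common grid."""


class DomainError(MonofilmError):
    """A physical quantity is outside its domain (non-positive splitting, eps_r <= 0...)."""


class KeyingError(ValidationError):
    """A required (system, parameter) key is missing from a table."""
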