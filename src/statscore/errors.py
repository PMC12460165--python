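"""Exception hierarchy shared across the pipeline stages.

``ValidationError`` and ``ConfigError`` indicate user-facing input problems
(CLI exit code 2); everything else derived from :class:`StatScoreError`
maps to a runtime failure (exit code 1).
"""


class StatScoreError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(StatScoreError):
    """Inputs are structurally inconsistent (cross-file, schema, invariants)."""


class ConfigError(ValidationError):
    """A configuration object or file violates its contract."""


class ParameterError(StatScoreError):
    """A numeric argument is outside its admissible domain."""


class ParseError(StatScoreError):
    """A text input file could not be parsed; message names the offending line."""


class DegenerateInputError(StatScoreError):
    """Input is formally valid but numerically degenerate (e.g. all-zero matrix)."""


class DegenerateCorrelationError(DegenerateInputError):
    """A correlation was requested on a zero-variance vector; caller decides policy."""
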