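"""Exception hierarchy.

Validation / format errors signal bad inputs (CLI exit code 2); computation
errors signal failures during an otherwise valid run (exit code 3).
"""


class CafluxError(Exception):
    """Base class for all package errors."""


class ValidationError(CafluxError, ValueError):
    """Invalid parameter, state, or configuration."""


class FormatError(CafluxError, ValueError):
    """Malformed input file or table."""


class IntegrationError(CafluxError, RuntimeError):
    """Numerical integration failed (non-finite or negative state)."""


class InsufficientDataError(CafluxError, RuntimeError):
    """Not enough periods / samples to compute the requested quantity."""


class DegenerateDataError(CafluxError, RuntimeError):
    """Statistic undefined on the given data (e.g. zero within-group variance)."""
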