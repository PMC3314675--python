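"""Exception types shared across the package."""


class CrossnormError(Exception):
    """Base class for all package errors."""


class ParseError(CrossnormError, ValueError):
    """A delimited input file could not be parsed."""


class ValidationError(CrossnormError, ValueError):
    """Inputs violate an invariant of the requested operation."""


class ConvergenceError(CrossnormError, RuntimeError):
    """An iterative fit failed to reach its tolerance."""
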