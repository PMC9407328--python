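"""Exception hierarchy shared across the pipeline stages."""


class CoexnetError(Exception):
    """Base class for all errors raised by coexnet."""


class FormatError(CoexnetError):
    """A file does not conform to the expected table layout."""


class ValidationError(CoexnetError):
    """Data violate a documented invariant (range, uniqueness, shape)."""


class ParameterError(CoexnetError):
    """A tunable is outside its admissible range or parameters are inconsistent."""


class ConvergenceError(CoexnetError):
    """An iterative computation failed to converge within its iteration budget."""
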