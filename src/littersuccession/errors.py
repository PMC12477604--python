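"""Exception hierarchy shared across the pipeline."""


class LitterSuccessionError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(LitterSuccessionError, ValueError):
    """A function argument is outside its documented domain."""


class FormatError(LitterSuccessionError, ValueError):
    """A file does not parse or violates the declared dialect."""


class ConsistencyError(LitterSuccessionError, ValueError):
    """Two inputs that must agree (e.g. table vs tree taxa) do not."""


class InputError(LitterSuccessionError, ValueError):
    """Data passed to an operation is degenerate (e.g. an all-zero sample)."""
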