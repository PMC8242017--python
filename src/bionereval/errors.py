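"""Exception hierarchy shared across the package."""


class BioNerEvalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BioNerEvalError, ValueError):
    """A file does not follow the expected tabular layout (e.g. missing column)."""


class EmptyInputError(BioNerEvalError, ValueError):
    """An input file or collection contains no usable records."""


class ValidationError(BioNerEvalError, ValueError):
    """Parsed data violate a domain invariant (self-loop, bad weight, conflict...)."""


class DomainError(BioNerEvalError, ValueError):
    """An operation was called outside its mathematical domain."""
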