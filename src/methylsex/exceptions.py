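"""Exception hierarchy.

``ValidationError`` means the inputs were malformed or violated a
precondition before any real computation started; ``EstimationError`` means
the computation itself could not produce a trustworthy answer (e.g. the
reference samples did not separate into two sex clusters). The CLI maps them
to exit codes 1 and 2 respectively.
"""


class MethylSexError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MethylSexError, ValueError):
    """Malformed input or violated precondition."""


class SchemeAlignmentError(ValidationError):
    """A requested bin edge does not coincide with a fine-panel edge."""


class EstimationError(MethylSexError, RuntimeError):
    """The estimation machinery failed (reference did not split, etc.)."""
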