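"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: argument errors -> 2, data/validation
errors -> 3, numerical failures -> 4.
"""


class GGCFlowError(Exception):
    """Base class for all package errors."""


class ArgumentError(GGCFlowError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class DataValidationError(GGCFlowError, ValueError):
    """Input data (mesh, matrix, table) fails an integrity check."""


class NumericalError(GGCFlowError, RuntimeError):
    """A solver failed to converge or produced non-finite output."""
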