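"""Exception hierarchy."""


class StrandflowError(Exception):
    """Base class for all package errors."""


class DomainError(StrandflowError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class InsufficientDataError(StrandflowError, ValueError):
    """Too few data points to perform the requested computation."""


class ConvergenceError(StrandflowError, RuntimeError):
    """An iterative computation failed to terminate within its budget."""


class StateError(StrandflowError, RuntimeError):
    """A query is inconsistent with the current state of the model."""
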