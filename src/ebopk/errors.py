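"""Exception hierarchy.

All package errors derive from :class:`EbopkError` so callers can catch one
base class; the subclasses also inherit the builtin they most resemble.
"""


class EbopkError(Exception):
    """Base class for all errors raised by ebopk."""


class ParameterError(EbopkError, ValueError):
    """A structural or population parameter violates its invariants."""


class InputError(EbopkError, ValueError):
    """Invalid input to a computation (unsorted times, bad dose event, ...)."""


class ContractError(EbopkError, ValueError):
    """An operation was called outside its contract (e.g. IV dose where PO required)."""


class DatasetError(EbopkError, ValueError):
    """A dataset failed schema or invariant validation."""


class FitError(EbopkError, RuntimeError):
    """Estimation could not be carried out."""
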