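"""Exception hierarchy shared across the package.

Three failure families are distinguished so callers can react sensibly:
configuration problems (bad settings or resources), data problems (a corpus
that violates its own invariants), and contract violations (a caller passed
something an operation's precondition forbids).
"""


class RetellError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RetellError):
    """A config file, backend resource, or option is malformed or missing."""


class DataError(RetellError):
    """A corpus or manifest violates a data invariant (e.g. duplicate days)."""


class ContractError(RetellError, ValueError):
    """An operation was called with input its precondition rules out."""
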