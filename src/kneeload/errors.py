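"""Exception hierarchy shared across the pipeline stages."""


class KneeloadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KneeloadError):
    """A configuration object violates its contract."""


class DomainError(KneeloadError):
    """An input value is outside the physically meaningful domain."""


class ContractError(KneeloadError):
    """A precondition between pipeline stages was violated."""


class DataError(KneeloadError):
    """A dataset is empty or degenerate where content is required."""


class FormatError(KneeloadError):
    """A motion-storage file is malformed; message names the offending line."""


class TrainingError(KneeloadError):
    """Model fitting diverged or failed; carries the training log."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


class NumericalError(KneeloadError):
    """A numerical routine failed to converge."""
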