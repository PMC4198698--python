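"""Exception hierarchy shared across the package."""


class FedvarError(Exception):
    """Base class for all package errors."""


class ValidationError(FedvarError):
    """Input failed a structural or value check (e.g. missing manifest field)."""


class ConflictError(FedvarError):
    """Operation would violate a uniqueness constraint."""


class AuthorizationError(FedvarError):
    """Caller lacks the role or grant required for the operation."""


class NotFoundError(FedvarError):
    """Referenced entity (user, sample, dataset, request) does not exist."""


class ConfigurationError(FedvarError):
    """Deployment configuration incomplete (e.g. missing chain for a build pair)."""


class NoDataError(FedvarError):
    """Pileup column is empty; caller should emit a no-call instead."""


class NotReadyError(FedvarError):
    """Results requested before every per-center task reached a terminal state."""
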