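"""Exception hierarchy shared across the package."""


class FatphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FatphError, ValueError):
    """A configuration object or parameter is invalid."""


class InputError(FatphError, ValueError):
    """A data input (patch, mask, curve, ...) violates its contract."""


class UsageError(FatphError, ValueError):
    """An operation was called in an unsupported way."""


class InvariantViolation(FatphError, RuntimeError):
    """A structural invariant (e.g. filtration monotonicity) is broken."""


class SizeError(FatphError, ValueError):
    """Input too large for an algorithm with an explicit size cap."""
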