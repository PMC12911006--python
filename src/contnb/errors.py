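"""Exception hierarchy shared across the package."""


class ContnbError(Exception):
    """Base class for all package-specific errors."""


class InputError(ContnbError, ValueError):
    """Malformed data: length mismatches, non-binary outcomes, bad columns."""


class DomainError(ContnbError, ValueError):
    """A numeric argument outside its mathematical domain."""


class ConfigError(ContnbError, ValueError):
    """Invalid weighting/simulation configuration."""


class DivergenceError(ContnbError, ValueError):
    """A required integral (e.g. the normalization integral of a weighting
    function) diverges.  Typically raised when a weighting density is
    positive at t=0 while the 1/t kernel is required; the remedy is a
    support bounded away from 0 or the difference form of the metric."""
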