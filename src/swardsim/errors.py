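"""Exception hierarchy shared by all simulator modules."""


class SwardsimError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(SwardsimError):
    """A run configuration value is missing, malformed or inconsistent."""


class FormatError(SwardsimError):
    """An input table does not match the declared column mapping."""


class ContinuityError(SwardsimError):
    """A weather series has a gap or out-of-order dates."""


class DomainError(SwardsimError, ValueError):
    """A physical quantity is outside its valid domain (e.g. negative radiation)."""


class NumericalError(SwardsimError):
    """A non-finite value appeared during integration; names quantity and date."""
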