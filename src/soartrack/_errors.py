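"""Exception hierarchy shared across the package."""


class SoartrackError(Exception):
    """Base class for all soartrack errors."""


class ConfigurationError(SoartrackError):
    """A config value or column mapping is missing or invalid."""


class DataError(SoartrackError):
    """Input data violate a structural requirement (e.g. non-monotone time)."""


class CoverageError(SoartrackError):
    """A queried coordinate falls outside the terrain grid."""


class ContractError(SoartrackError):
    """A documented precondition of an operation was violated by the caller."""
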