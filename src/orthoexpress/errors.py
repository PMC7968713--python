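"""Exception hierarchy shared by all pipeline stages."""


class OrthoExpressError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OrthoExpressError, ValueError):
    """An invalid parameter combination was supplied."""


class EmptyResultError(OrthoExpressError, ValueError):
    """An operation produced an empty result where data is required."""


class UndefinedStatisticError(OrthoExpressError, ValueError):
    """A statistic is mathematically undefined for the given input."""
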