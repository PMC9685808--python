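"""Exception hierarchy shared across the package."""


class FluorosynthError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FluorosynthError):
    """An external file violates its expected format (shape, dtype, dialect)."""


class ContractError(FluorosynthError, ValueError):
    """An in-memory object violates a documented invariant."""


class InsufficientDataError(FluorosynthError):
    """Too few pixels/records to compute the requested statistic."""


class ConfigError(FluorosynthError, ValueError):
    """A run configuration is missing or malformed; message names the field."""
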