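"""Exception hierarchy shared by all pipelines."""


class FluoroquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FluoroquantError):
    """An input file could not be read as a supported image format."""


class ConfigurationError(FluoroquantError):
    """Inconsistent or invalid parameters (e.g. channel-role mismatch)."""


class DegenerateInputError(FluoroquantError):
    """Input carries no usable contrast (e.g. constant image for Otsu)."""


class UndefinedStatisticError(FluoroquantError):
    """A statistic is mathematically undefined on this input.

    Reported as missing by pipeline drivers; never silently coerced to 0.
    """


class NoSignalError(FluoroquantError):
    """No foreground signal where at least one object is required."""


class DensityError(FluoroquantError):
    """Synthetic-field placement failed within the retry budget."""
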