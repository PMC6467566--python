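"""Exception hierarchy shared across the package."""


class AudassocError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AudassocError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedRatioError(AudassocError):
    """A ratio statistic could not be formed (zero denominator after flooring)."""


class MissingEventError(AudassocError, KeyError):
    """An analysis window anchor could not be resolved against trial events."""


class MissingDataError(AudassocError):
    """A requested window is not covered by the recorded samples."""


class ValidationError(AudassocError):
    """A session bundle or configuration failed schema/integrity validation."""


class ConfigError(AudassocError, ValueError):
    """A run or session configuration is internally inconsistent."""
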