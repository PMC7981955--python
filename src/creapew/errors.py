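"""Exception hierarchy shared across the package."""


class CreapewError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CreapewError, ValueError):
    """An input is outside the mathematical/physiological domain of an operation."""


class SeparationError(CreapewError, RuntimeError):
    """Logistic fit shows (quasi-)complete separation; estimates are not reportable."""


class RankDeficiencyError(CreapewError, ValueError):
    """Design matrix is rank deficient (e.g. duplicated covariate)."""


class UnitMismatchError(CreapewError, ValueError):
    """A table header carries a unit suffix different from the documented schema."""


class SchemaError(CreapewError, ValueError):
    """A mandatory column is missing or a table violates its schema."""


class ConfigError(CreapewError, ValueError):
    """Invalid or unknown configuration keys/values."""
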