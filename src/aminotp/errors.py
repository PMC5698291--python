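"""Exception hierarchy shared across the package."""


class AminotpError(Exception):
    """Base class for all package errors."""


class SchemaError(AminotpError):
    """An input table is missing a mandatory column or has an unusable header."""


class ValidationError(AminotpError):
    """Row- or value-level problem: duplicate ids, unparseable numbers, bad parameters."""


class DomainError(AminotpError):
    """A parameter is outside the mathematical domain of an operation (e.g. TDF <= 0)."""


class ConfigError(AminotpError):
    """A configuration value is inconsistent (e.g. a bulk-isotope rectangle outside its class region)."""


class InferenceError(AminotpError):
    """Not enough eligible data for a statistical procedure."""


class PlausibilityWarning(UserWarning):
    """Isotope value outside the plausible range; the value is kept."""
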