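"""Exception hierarchy shared across the package."""


class SparsePKError(Exception):
    """Base class for all package errors."""


class ParameterError(SparsePKError):
    """A pharmacokinetic or statistical parameter is out of its valid domain."""


class ConfigurationError(SparsePKError):
    """A user-supplied configuration value is invalid."""


class SchemaError(SparsePKError):
    """A dataset file does not match the documented column schema."""


class InputError(SparsePKError):
    """Runtime inputs are inconsistent with each other (e.g. scaler mismatch)."""


class DimensionError(SparsePKError):
    """Array shapes are mutually inconsistent."""


class FitError(SparsePKError):
    """Model estimation failed irrecoverably."""
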