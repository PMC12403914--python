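"""Exception hierarchy shared across the pipeline."""


class HfoCouplingError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HfoCouplingError):
    """A parameter set violates its documented constraints."""


class ValidationError(HfoCouplingError):
    """Input data violate a documented contract."""


class SchemaError(ValidationError):
    """A tabular file is missing required columns or has malformed rows."""


class OutOfRangeError(ValidationError):
    """An injected atom or requested interval does not fit in the recording."""


class InputTooShortError(ValidationError):
    """The signal is shorter than the filter transient it must absorb."""
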