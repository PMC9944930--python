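"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid simulation, model, or consensus configuration."""


class SamplingError(ValueError):
    """A requested sample cannot be drawn from the available cohort."""


class SchemaError(KeyError):
    """An input table is missing a required column."""


class UnsupportedBackendError(TypeError):
    """The requested operation is not defined for this model backend."""
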