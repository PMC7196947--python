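"""Exception hierarchy for revlearn."""


class RevlearnError(Exception):
    """Base class for all revlearn errors."""


class ParameterError(RevlearnError):
    """A parameter set is invalid for the requested model."""


class DataError(RevlearnError):
    """Trial data violate the session contract (bad codes, inconsistent replay)."""


class SchemaError(DataError):
    """A session/results file does not match the expected schema."""


class ConfigError(RevlearnError):
    """A configuration value (grid, measure name, model name) is invalid."""
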