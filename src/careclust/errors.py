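"""Exception hierarchy shared across the pipeline stages."""


class CareclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CareclustError, ValueError):
    """Invalid configuration (bad probabilities, rates, shapes, paths)."""


class DegenerateSizeError(ConfigurationError):
    """A requested problem size cannot support the requested structure."""


class SchemaError(CareclustError, KeyError):
    """An input table is missing a required field."""


class PoolingError(CareclustError, ValueError):
    """Rubin pooling asked for with fewer than two completed datasets."""


class StageError(CareclustError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
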