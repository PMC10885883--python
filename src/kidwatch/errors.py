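"""Exception hierarchy shared across the pipeline stages."""


class KidwatchError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(KidwatchError):
    """A configuration value violates one of its stated invariants."""


class SchemaError(KidwatchError):
    """An input file does not match the expected column schema."""


class InsufficientDataError(KidwatchError):
    """Too few observations for the requested statistic."""


class SingleClassError(KidwatchError):
    """An operation requiring both behavior classes received only one."""


class EmptyClassError(KidwatchError):
    """A requested label produced zero samples."""


class MisalignedLabelsError(KidwatchError):
    """A label sequence does not align one-to-one with its record stream."""


class ContextMismatchError(KidwatchError):
    """Group statistics were passed with the wrong labor/non-labor context."""


class MissingArtifactError(KidwatchError):
    """A required upstream artifact (model, calibration, data file) is absent."""
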