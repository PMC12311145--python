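"""Exception hierarchy shared across the pipeline.

Every stage raises one of these so the CLI can map failures to exit codes
(2 = config, 3 = data, 4 = stage computation).
"""


class MirvError(Exception):
    """Base class for all package errors."""


class ConfigError(MirvError):
    """Invalid or inconsistent run configuration."""


class SchemaError(MirvError):
    """Input table does not match the declared column schema."""


class DataIntegrityError(MirvError):
    """Input table violates an invariant (duplicates, missing values, bad ranges)."""


class StageError(MirvError):
    """A pipeline stage could not produce a result (e.g. no features survive)."""
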