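"""Exception hierarchy shared across the pipeline stages.

Each class maps to a distinct CLI exit code (see :mod:`mirlink.cli`).
"""


class MirlinkError(Exception):
    """Base class for all package errors."""


class ConfigError(MirlinkError):
    """Invalid configuration value or unknown configuration key."""


class FormatError(MirlinkError):
    """Malformed input file (duplicate ids, bad alphabet, missing columns)."""


class ParameterError(MirlinkError):
    """Operation parameter outside its documented range."""


class PlacementError(MirlinkError):
    """A planted sequence feature could not be placed without overlap."""


class ConstantSeriesError(MirlinkError):
    """Pearson correlation requested on a zero-variance trajectory."""


class GridMismatchError(MirlinkError):
    """Two trajectories do not share the same timepoint grid."""


class PipelineError(MirlinkError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
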