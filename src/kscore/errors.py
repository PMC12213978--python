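"""Exception taxonomy shared across the pipeline.

All package errors derive from :class:`KScoreError` so callers can catch the
package's failures without masking programming errors.
"""


class KScoreError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KScoreError):
    """A file's header/columns do not match the declared trajectory schema."""


class DataError(KScoreError):
    """File contents violate data-level constraints (gaps, timestamps, ...)."""


class ParameterError(KScoreError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(KScoreError):
    """Input carries no usable signal (zero variance, constant sample, ...)."""


class SegmentationError(KScoreError):
    """Sit-to-stand segmentation could not produce the required repetitions."""


class ModelStateError(KScoreError):
    """A model object is missing state required by the requested operation."""


class ModelError(KScoreError):
    """A statistical model cannot be fit on the given design."""


class ConvergenceError(ModelError):
    """An iterative fit failed to converge; carries optimizer diagnostics."""


class RangeError(KScoreError, ValueError):
    """A measurement lies outside its physically valid range."""


class PipelineError(KScoreError):
    """A pipeline stage failed; names the stage and the offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
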