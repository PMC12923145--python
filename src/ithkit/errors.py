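"""Exception hierarchy shared across the pipeline.

Every stage of :func:`ithkit.topology_score.compute_ith` raises (or wraps
into) a :class:`StageError` subtype so callers and the CLI can name the
failing stage.
"""


class IthKitError(Exception):
    """Base class for all package errors."""


class AlignmentError(IthKitError):
    """Image and mask do not live on the same grid (shape/spacing mismatch)."""


class DegenerateInputError(IthKitError):
    """Input is structurally valid but too small/empty for the operation."""


class UnsupportedModelError(IthKitError):
    """The SHAP engine does not know how to decompose this model type."""


class PackingError(IthKitError):
    """Phantom blob placement could not satisfy the requested topology."""


class StageError(IthKitError):
    """Wraps a failure with the name of the pipeline stage that produced it."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
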