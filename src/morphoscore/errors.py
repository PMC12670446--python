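"""Exception hierarchy shared across the pipeline."""


class MorphoscoreError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MorphoscoreError):
    """Invalid landmark configuration, bilateral map, or cohort spec."""


class DegenerateConfigurationError(ConfigurationError):
    """All points coincident; centroid size is zero."""


class ShapeMismatchError(MorphoscoreError):
    """Operands have incompatible landmark counts or dimensions."""


class InsufficientDataError(MorphoscoreError):
    """Too few samples for the requested operation."""


class SingularDesignError(MorphoscoreError):
    """Rank-deficient regression design matrix.

    Carries the name of the offending column when it can be identified.
    """

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class DegenerateAxisError(MorphoscoreError):
    """Group coefficient vector has (numerically) zero norm."""


class DegenerateReferenceError(MorphoscoreError):
    """Reference group has zero score variance; cannot standardize."""


class SingularCovarianceError(MorphoscoreError):
    """Sample covariance of paired differences is singular."""


class DegreesOfFreedomError(MorphoscoreError):
    """Not enough pairs for the requested number of dimensions."""


class StageError(MorphoscoreError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
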