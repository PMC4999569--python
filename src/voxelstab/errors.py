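"""Exception hierarchy for configuration and pipeline failures."""


class VoxelStabError(ValueError):
    """Base class for all package-specific errors."""


class InvalidSpecError(VoxelStabError):
    """A synthetic-data specification violates its invariants."""


class DesignError(VoxelStabError):
    """An experiment design is internally inconsistent or unfittable."""


class RankDeficiencyError(VoxelStabError):
    """A GLM design matrix is rank deficient; carries the offending columns."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns is not None else ()


class ParameterError(VoxelStabError):
    """A hyperparameter is outside its valid range."""


class DegenerateLabelsError(VoxelStabError):
    """Labels carry no class contrast (e.g., a single class present)."""


class SchemeError(VoxelStabError):
    """A cross-validation or resampling scheme cannot be realised."""


class StabilityIterationError(VoxelStabError):
    """A selector failed inside the resampling loop; carries the iteration."""

    def __init__(self, iteration: int, cause: Exception):
        super().__init__(
            f"selector failed at resampling iteration {iteration}: {cause}"
        )
        self.iteration = iteration
        self.__cause__ = cause
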