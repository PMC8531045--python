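"""Exception hierarchy for the deliriscore pipeline."""


class DeliriScoreError(Exception):
    """Base class for all package errors."""


class CohortParseError(DeliriScoreError):
    """Malformed cohort CSV (tokenization / structural problems)."""


class CohortValidationError(DeliriScoreError):
    """Cohort content violates the variable registry contract."""


class ConfigurationError(DeliriScoreError):
    """Invalid specification, registry rule, or pipeline configuration."""


class ScreeningError(DeliriScoreError):
    """Univariate screening cannot proceed (degenerate outcome, empty input)."""


class SearchError(DeliriScoreError):
    """Score enumeration / exhaustive search constraint violation."""


class ScoringError(DeliriScoreError):
    """A score definition cannot be applied to a cohort."""


class UndefinedAUCError(DeliriScoreError):
    """AUC requested with a single-class outcome."""


class ValidationStageError(DeliriScoreError):
    """External-validation computation cannot proceed."""


class NumericError(DeliriScoreError):
    """Numerical routine failed to converge; message carries diagnostics."""


class PipelineError(DeliriScoreError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
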