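"""Exception hierarchy shared across the pipeline."""


class CernetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CernetError, ValueError):
    """A file or table violates the documented format contract."""


class UsageError(CernetError, ValueError):
    """An operation was called with arguments outside its contract."""


class ConfigurationError(CernetError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class ConsistencyError(CernetError, ValueError):
    """Cross-referenced inputs disagree (e.g. unknown gene ids)."""


class NormalizationError(CernetError, ValueError):
    """Scaling-factor computation failed for a sample."""


class EstimationError(CernetError, ValueError):
    """A statistical estimator received degenerate input."""


class DegenerateSplitError(UsageError):
    """A median split is impossible (all values identical)."""


class PipelineStageError(CernetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
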