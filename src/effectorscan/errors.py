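"""Exception hierarchy shared across the pipeline."""


class EffectorScanError(Exception):
    """Base class for all pipeline errors."""


class InputError(EffectorScanError):
    """Malformed or inconsistent input data (bad value, orphan sample, ...)."""


class ConfigError(EffectorScanError):
    """Invalid run or simulation configuration."""


class DegenerateDistributionError(EffectorScanError):
    """A statistic cannot be formed because the data carry no dispersion.

    Raised e.g. when every candidate gene has identical expression, so the
    standard score is undefined and no high-expression call is possible.
    """


class NoInformationError(EffectorScanError):
    """A test has no usable observations (e.g. all differences are zero)."""


class StageError(EffectorScanError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
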