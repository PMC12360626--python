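"""Exception hierarchy for the oepsc package."""


class OepscError(Exception):
    """Base class for all package errors."""


class FormatError(OepscError):
    """A file does not conform to the declared sweep-set layout."""


class ParameterError(OepscError, ValueError):
    """An argument violates an operation's preconditions."""


class DataError(OepscError, ValueError):
    """Input data are internally inconsistent or physically impossible."""


class UndefinedLatencyError(OepscError):
    """A trace never reaches the rise-fraction threshold, so onset latency is undefined."""


class FitError(OepscError):
    """A model fit failed to converge."""

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class NoBimodalityError(FitError):
    """The latency histogram shows no evidence of two populations."""


class NoTroughError(OepscError):
    """The fitted double Gaussian has no interior minimum between its component means."""


class PipelineStageError(OepscError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage, message):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
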