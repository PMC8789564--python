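"""Exception hierarchy shared across the pipeline."""


class HippostateError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HippostateError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(HippostateError, ValueError):
    """Input is formally valid but carries no usable structure (e.g. zero variance)."""


class InsufficientDataError(HippostateError, ValueError):
    """Not enough samples / bins / frames to run the operation."""


class MissingMetricError(HippostateError, KeyError):
    """A required per-unit or per-ROI quality metric is absent."""


class UndefinedGainError(HippostateError, ZeroDivisionError):
    """Gain factor requested for two zero rates."""


class EmptyResultError(HippostateError, ValueError):
    """Every element was filtered out, leaving nothing to analyse."""


class NonConvergenceError(HippostateError, RuntimeError):
    """Iterative algorithm hit its iteration cap without converging."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter
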