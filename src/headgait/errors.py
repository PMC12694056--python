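"""Exception hierarchy shared across the package."""


class HeadgaitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeadgaitError):
    """Input file does not conform to the expected tabular layout."""


class InsufficientDataError(HeadgaitError):
    """Too few samples for the requested operation."""


class InputError(HeadgaitError):
    """Invalid argument or signal (non-increasing time base, bad window, ...)."""


class TrialExcludedError(HeadgaitError):
    """Trial fails a data-quality rule (e.g. >10% missing samples).

    Carries the offending missing fraction so pipelines can log the reason.
    """

    def __init__(self, message: str, missing_frac: float | None = None):
        super().__init__(message)
        self.missing_frac = missing_frac


class AlignmentError(HeadgaitError):
    """Cross-correlation alignment left less than the minimum overlap."""


class OptimizationError(HeadgaitError):
    """Threshold grid search could not evaluate any candidate."""
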