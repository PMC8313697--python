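"""Exception hierarchy shared across the package.

Rejection of a single EMG trial is *data*, not an error, and is reported
through flags on the feature record; the exceptions here signal misuse of
an operation or data that cannot be analysed at all.
"""


class StopCSPError(Exception):
    """Base class for all package errors."""


class ParameterError(StopCSPError, ValueError):
    """A configuration or parameter object violates its invariants."""


class AnalysisError(StopCSPError, ValueError):
    """A table or summary cannot be analysed (e.g. no stop trials)."""


class EstimationError(AnalysisError):
    """An estimator's preconditions are not met (e.g. no responded go trials)."""


class DetectionError(StopCSPError, ValueError):
    """An EMG landmark (MEP, end of silent period) could not be located."""


class ValidationError(StopCSPError, ValueError):
    """A file fails schema validation; message carries the offending row."""
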