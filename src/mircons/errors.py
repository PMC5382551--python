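"""Exception hierarchy.

Every error raised by the library derives from :class:`MirconsError`, so the
CLI can map any failure to a single-line ``error-class: message`` on stderr
and a nonzero exit status.
"""


class MirconsError(Exception):
    """Base class for all mircons errors."""


class ParameterError(MirconsError, ValueError):
    """Invalid numeric/shape parameter passed to a generator or estimator."""


class ConfigurationError(MirconsError, ValueError):
    """Inconsistent run configuration (missing reference gene, empty coupling...)."""


class PlantingError(MirconsError, ValueError):
    """Requested site/motif planting density is infeasible for the sequence length."""


class EstimationError(MirconsError, ValueError):
    """Degenerate data defeats a statistical estimator."""


class ScalingError(MirconsError, ValueError):
    """Between-array scaling impossible (e.g. a zero-MAD array)."""


class DesignError(MirconsError, ValueError):
    """Rank-deficient or under-determined design matrix."""


class ParseError(MirconsError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AnalysisError(MirconsError, ValueError):
    """A statistic is undefined for the given data (constant vector, empty group...)."""
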