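"""Exception hierarchy.

All library errors derive from :class:`KspectraError` so callers (and the CLI)
can distinguish user/input problems from pipeline-stage failures.
"""


class KspectraError(Exception):
    """Base class for all kspectra errors."""


class InvalidSpecError(KspectraError, ValueError):
    """A simulation spec or configuration violates its invariants."""


class HistogramParseError(KspectraError, ValueError):
    """A ``.histo`` file line could not be parsed.

    Carries the 1-based line number in :attr:`lineno`.
    """

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class NoCutoffError(KspectraError):
    """The k-mer histogram decreases monotonically: no error/genomic valley.

    Typically means coverage is too low for spectrum analysis; resequence at
    higher depth (>10x) or lower k.
    """


class NoPairsError(KspectraError):
    """No heterozygous k-mer pairs found in the retained coverage window."""


class FitConvergenceError(KspectraError):
    """The spectrum mixture fit failed to converge from any start point.

    Carries the best (smallest) weighted residual seen in :attr:`best_residual`.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        super().__init__(message)


class PipelineStageError(KspectraError):
    """A pipeline stage failed; :attr:`stage` names it. Partial outputs are kept."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
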