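"""Exception hierarchy shared across the package."""


class StresscastError(Exception):
    """Base class for package-specific errors."""


class DomainError(StresscastError, ValueError):
    """A value falls outside its declared domain (e.g. stress level not in 0..5)."""


class ParseError(StresscastError, ValueError):
    """An input file is malformed; the message names the offending row."""


class InsufficientDataError(StresscastError, ValueError):
    """The sequence is too short for the requested operation."""


class EstimationError(StresscastError, RuntimeError):
    """A numerical estimate (neighbor statistics, slope fit) is undefined."""


class SearchError(StresscastError, RuntimeError):
    """A neighbor search has an empty candidate set."""


class PredictionError(StresscastError, RuntimeError):
    """A forecast step cannot be computed (e.g. no neighbor has a successor)."""
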