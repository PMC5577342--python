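"""Exception hierarchy shared across the package."""


class RhinocastError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RhinocastError, ValueError):
    """A simulation or pipeline parameter violates its invariants."""


class DegenerateSeriesError(RhinocastError, ValueError):
    """A time series is constant (or otherwise too degenerate to analyse)."""


class MissingDataError(RhinocastError, ValueError):
    """Required daily records are absent; imputation is never silent."""


class EstimationError(RhinocastError, RuntimeError):
    """A least-squares fit failed (singular design, no usable rows, ...)."""


class DomainError(RhinocastError, ValueError):
    """An input lies outside the mathematical domain of an operation."""
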