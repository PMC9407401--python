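"""Exception hierarchy for boldcomplexity."""


class BoldComplexityError(Exception):
    """Base class for all package errors."""


class DegenerateSeriesError(BoldComplexityError):
    """A time series has no usable fluctuation (constant or pure trend)."""


class SimulationError(BoldComplexityError):
    """A synthetic-data generator could not honour its contract."""


class ValidationError(BoldComplexityError, ValueError):
    """An input violates a documented precondition."""
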