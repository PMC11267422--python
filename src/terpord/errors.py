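"""Exception types shared across the package."""


class TerpordError(ValueError):
    """Base class for validation and analysis errors."""


class FormatError(TerpordError):
    """An input file violates the expected tabular layout."""


class RangeError(TerpordError):
    """A query falls outside the tabulated range (extrapolation refused)."""


class DegeneracyError(TerpordError):
    """A statistic is undefined for the given data (singular covariance,
    identical anchors, coincident points, ...)."""
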