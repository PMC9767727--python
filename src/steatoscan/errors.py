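"""Exception hierarchy shared across the pipeline stages."""


class SteatoscanError(Exception):
    """Base class for all package errors."""


class ParameterError(SteatoscanError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DimensionError(SteatoscanError, ValueError):
    """A requested image/array dimension is non-positive or inconsistent."""


class ConfigurationError(SteatoscanError, ValueError):
    """A configuration object is incomplete or self-contradictory."""


class EmptyExtractionError(SteatoscanError, ValueError):
    """A region of interest is too small to yield a single window."""


class DegenerateGroupError(SteatoscanError, ValueError):
    """A two-class group has an empty class, so group statistics are undefined."""


class LeakageError(SteatoscanError, ValueError):
    """A differential patch's parent ended up on the test side of a split."""


class ShapeError(SteatoscanError, ValueError):
    """Layer shapes do not propagate consistently through an architecture."""


class DataError(SteatoscanError, ValueError):
    """A dataset is empty or carries labels outside the known classes."""


class DivergenceError(SteatoscanError, RuntimeError):
    """Training produced a non-finite loss."""
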