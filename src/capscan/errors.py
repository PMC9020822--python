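"""Exception hierarchy shared across the pipeline stages."""


class CapscanError(Exception):
    """Base class for all capscan errors."""


class ValidationError(CapscanError, ValueError):
    """A parameter or input violates its documented contract."""


class GeometryError(CapscanError):
    """Nucleus geometry is inconsistent with the image canvas or degenerate."""


class TracingError(CapscanError):
    """No nuclear-envelope ring could be recovered from the image."""


class BorderError(CapscanError):
    """Profile sampling positions fall outside the image."""


class UndefinedRatioError(CapscanError):
    """A ratio statistic has a non-positive denominator; the cell is excluded."""


class DegenerateProfileError(CapscanError):
    """A constant intensity profile makes the Pearson correlation undefined."""


class EstimationError(CapscanError):
    """A survival curve cannot be estimated (e.g. no observed events)."""
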