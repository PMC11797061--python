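"""Exception hierarchy shared across the toolkit."""


class IvtkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(IvtkitError):
    """Malformed input file or structure string."""


class IntegrityError(IvtkitError):
    """Data violates a table invariant (e.g. mutations > coverage)."""


class ParameterError(IvtkitError):
    """Invalid parameter value passed to a generator or estimator."""


class InsufficientDataError(IvtkitError):
    """Too few observations to carry out the requested computation."""


class DegenerateScaleError(IvtkitError):
    """Normalization scale is zero (Q3 == Q1)."""


class FitError(IvtkitError):
    """Curve fit failed to converge or the model is unidentifiable."""


class PlacementError(IvtkitError):
    """Synthetic objects could not be placed without overlap."""
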