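"""Exception hierarchy for the package."""


class NetquantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetquantError, ValueError):
    """Malformed inputs: out-of-bounds annotations, unknown labels, bad specs."""


class PlacementError(NetquantError, RuntimeError):
    """A synthetic field could not place all nuclei under its constraints."""


class SamplingError(NetquantError, RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


class LeakageError(NetquantError, RuntimeError):
    """An operation would mix training and held-out data."""


class FitError(NetquantError, RuntimeError):
    """A curve fit failed to converge."""


class DegenerateNormalizationError(NetquantError, ValueError):
    """Dose-response normalisation undefined (all group means equal)."""


class NoThresholdError(NetquantError, ValueError):
    """Isodata thresholding undefined (constant image)."""


class DegenerateResampleError(NetquantError, RuntimeError):
    """Marginal matching emptied one of the record sets."""
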