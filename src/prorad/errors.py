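"""Exception hierarchy for the pipeline.

All errors raised by prorad derive from :class:`ProradError` so callers can
catch pipeline failures without masking programming errors.
"""


class ProradError(Exception):
    """Base class for all prorad errors."""


class ConfigurationError(ProradError):
    """Invalid configuration: overlapping regions, bad thresholds, bad seeds."""


class DegenerateInputError(ProradError):
    """Input is structurally valid but carries no usable signal
    (e.g. an all-zero enhancement matrix)."""


class FactorizationError(ProradError):
    """Temporal-pattern factorization failed to converge."""

    def __init__(self, message: str, n_iter: int | None = None,
                 reconstruction_err: float | None = None):
        super().__init__(message)
        self.n_iter = n_iter
        self.reconstruction_err = reconstruction_err


class MaskError(ProradError):
    """A mask violates a containment or shape contract."""


class RegionStatsError(ProradError):
    """A region is too small or ill-conditioned for the requested statistic."""
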