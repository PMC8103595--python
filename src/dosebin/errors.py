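"""Exception hierarchy for the dose-response pipeline."""


class DosebinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DosebinError, ValueError):
    """Invalid simulation or pipeline configuration."""


class AggregationError(DosebinError, ValueError):
    """Person-year aggregation failed (e.g. non-constant covariate within a stratum key)."""


class BinningError(DosebinError, ValueError):
    """Exposure binning failed (degenerate cut points, non-finite exposures, empty bins)."""


class EstimationError(DosebinError, RuntimeError):
    """Model estimation failed (missing classes, zero-death bins, non-convergence)."""
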