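"""Exception hierarchy shared across the pipeline stages."""


class CochlearAgingError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CochlearAgingError):
    """Invalid study design, thresholds, or pipeline configuration."""


class FormatError(CochlearAgingError):
    """Malformed input table (duplicate gene, non-numeric cell, empty file...)."""


class ProtocolError(CochlearAgingError):
    """Invalid stimulus protocol (sample rate too low, non-integer cycles...)."""


class SpectralLeakageError(ProtocolError):
    """Requested frequency does not fit an integer number of cycles in the window."""


class ModelMismatchError(CochlearAgingError):
    """No RC circuit model is consistent with a measured admittance pair."""


class FitError(CochlearAgingError):
    """Nonlinear fit failed to converge from every starting point."""
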