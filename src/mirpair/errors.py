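"""Exception types shared across the pipeline stages."""


class MirpairError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MirpairError):
    """An input value or table violates a documented contract."""


class NormalizationError(MirpairError):
    """Size-factor estimation is impossible (no feature with all-positive counts)."""


class DesignError(MirpairError):
    """The model design matrix is unusable (e.g. rank deficient)."""
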