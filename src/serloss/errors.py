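"""Exception hierarchy for the serloss pipeline."""


class SerlossError(Exception):
    """Base class for all package errors."""


class ConfigError(SerlossError):
    """Invalid configuration; the message names the offending field."""


class DimensionError(SerlossError):
    """Grid shapes or block factors do not line up."""


class FormatError(SerlossError):
    """A file on disk does not match the declared layout."""


class GenerationError(SerlossError):
    """The synthetic generator cannot satisfy the request."""


class FitError(SerlossError):
    """GLM fitting failed (non-convergence, with iteration context)."""


class SingularDesignError(FitError):
    """Design matrix is rank deficient / separated."""


class PipelineError(SerlossError):
    """A pipeline stage cannot proceed (e.g. no wilderness anywhere)."""


class ValidationError(SerlossError):
    """Validation domain is degenerate (empty mask, zero variance)."""
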