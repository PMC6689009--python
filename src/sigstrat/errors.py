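"""Exception types shared across the pipeline."""


class SigstratError(Exception):
    """Base class for all package errors."""


class ConfigError(SigstratError, ValueError):
    """A generator or analysis configuration violates its invariants."""


class ValidationError(SigstratError, ValueError):
    """Input data violates a documented precondition."""


class EmptySignatureError(SigstratError):
    """Signature construction produced no genes in either template."""


class FitError(SigstratError, RuntimeError):
    """A model fit could not be performed (too few usable points, no convergence)."""
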