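"""Exception types shared across the pipeline."""


class SipCopError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SipCopError, ValueError):
    """Input violates a documented invariant (bad landmark, bad factor level...)."""


class DegenerateInputError(SipCopError, ValueError):
    """Structurally valid input that carries no usable signal (all-zero frame,
    zero CoP variance, constant angles...)."""


class SingularConfigurationError(SipCopError, ZeroDivisionError):
    """Beam-model parameters hit the singular denominator of the proportional
    pressure expression."""


class NoReductionError(DegenerateInputError):
    """Trial shows no seat-interface-pressure reduction; it must be excluded
    rather than truncated."""


class MissingTermError(SipCopError, KeyError):
    """A slope composition or threshold was requested for an effect the fitted
    model does not contain."""


class SingleLevelFactorError(ValidationError):
    """A categorical fixed effect was requested but only one level is observed."""
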