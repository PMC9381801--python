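"""Exception types shared across the package."""


class SupportError(ValueError):
    """Input lies outside the support/domain of a distribution or operation."""


class FitError(RuntimeError):
    """A maximum-likelihood fit failed to converge or was degenerate."""


class UnsupportedOperationError(RuntimeError):
    """The requested operation is not defined for this model (e.g. the
    h-function of the comonotonic copula, whose derivative is a step)."""


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""
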