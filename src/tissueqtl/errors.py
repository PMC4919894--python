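"""Exception types raised by tissueqtl."""


class TissueQTLError(Exception):
    """Base class for all tissueqtl errors."""


class DegenerateDataError(TissueQTLError):
    """Input carries no usable signal (constant expression, unidentifiable tau, ...)."""


class InvalidCovarianceError(TissueQTLError):
    """Covariance parameters violate positivity constraints."""


class ConvergenceError(TissueQTLError):
    """Null-model optimiser failed to converge.

    Carries the iteration trace (list of (tau, epsilon, loglik) triples) in
    ``trace`` for post-mortem inspection.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SubjectMismatchError(TissueQTLError):
    """Expression and genotype subject universes disagree; message lists the difference."""


class CollinearCovariatesError(TissueQTLError):
    """Covariate design is rank deficient; message names the collinear columns."""
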