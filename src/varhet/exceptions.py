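"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`VarhetError`,
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class VarhetError(Exception):
    """Base class for all errors raised by varhet."""


class ParameterError(VarhetError, ValueError):
    """A distribution or test parameter is outside its valid range."""


class SupportError(VarhetError, ValueError):
    """Data fall outside the support of the requested family."""


class DegenerateDataError(VarhetError, ValueError):
    """Data carry no usable signal for the operation (e.g. zero variance)."""


class InfeasibleEffectError(VarhetError, ValueError):
    """Requested mean/sd combination cannot be realised by the family."""


class ConvergenceError(VarhetError, RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateFitError(VarhetError, RuntimeError):
    """Every EM restart collapsed (vanishing weight or spread floor hit)."""


class DesignError(VarhetError, ValueError):
    """Test and study design are incompatible (e.g. >2 groups)."""


class DataSchemaError(VarhetError, ValueError):
    """An input table does not match the expected schema."""


class IncompletePairError(VarhetError, ValueError):
    """A twin pair is missing one member or its covariate."""
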