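"""Exception hierarchy shared across the package."""


class NdfsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NdfsError, ValueError):
    """A model parameter violates its physical constraint (e.g. Lc <= 0)."""


class DomainError(NdfsError, ValueError):
    """An evaluation point lies outside the function's domain of validity."""


class InputError(NdfsError, ValueError):
    """Malformed or empty user-supplied data (angle tables, configs)."""


class EstimationError(NdfsError, RuntimeError):
    """An estimator cannot be computed from the data provided."""


class ModelError(NdfsError, RuntimeError):
    """A model prediction degenerated (e.g. zero probability everywhere)."""
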