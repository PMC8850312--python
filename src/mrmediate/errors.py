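"""Exception hierarchy shared across the pipeline."""


class MrMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrMediateError):
    """A configuration value or column mapping is unusable."""


class InputError(MrMediateError, ValueError):
    """Input data violate a precondition (empty file, zero overlap, bad SE...)."""


class EstimationError(MrMediateError):
    """Estimation is impossible on the given inputs (no instruments left, all outliers...)."""


class ConvergenceError(MrMediateError):
    """An iterative fit failed to converge; carries diagnostics in args."""
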