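"""Exception hierarchy shared across the package.

Every precondition violation raises a subclass of :class:`PunctatrackError`,
so callers can catch one base class at pipeline level.
"""


class PunctatrackError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParamsError(PunctatrackError, ValueError):
    """Simulation or metric parameters violate their stated invariants."""


class FormatError(PunctatrackError, ValueError):
    """An input table or file does not have the required layout."""


class DegenerateInputError(PunctatrackError, ValueError):
    """Input is structurally valid but the quantity is undefined on it
    (e.g. an all-zero image passed to the median-ratio transform)."""


class DegenerateBaselineError(DegenerateInputError):
    """A baseline (pre-event or cytosolic reference) mean is non-positive,
    so a fold change or enrichment ratio cannot be formed."""


class InsufficientRoiError(PunctatrackError, ValueError):
    """A region of interest is empty or too small for the requested metric."""


class UndefinedCorrelationError(DegenerateInputError):
    """Pearson correlation requested on a channel with zero variance."""


class ConfigError(PunctatrackError, ValueError):
    """A run configuration failed schema validation."""
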