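"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`CnMotionError`, so callers (and the CLI) can distinguish validation
problems from genuine bugs.
"""


class CnMotionError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CnMotionError, ValueError):
    """A model or configuration parameter violates its constraints."""


class ShapeError(CnMotionError, ValueError):
    """Array dimensions are inconsistent with the model structure."""


class DataError(CnMotionError, ValueError):
    """Input data contain non-finite values or violate invariants."""


class IntegrationError(CnMotionError, RuntimeError):
    """The ODE solver failed or the trajectory blew up."""


class DomainError(CnMotionError, ValueError):
    """The requested quantity is undefined for these inputs
    (e.g. a pendulum orbit in the rotation regime has no libration period)."""


class DegenerateCentersError(CnMotionError, ValueError):
    """All radial-basis centers coincide; no length scale can be inferred."""


class DegenerateChannelError(CnMotionError, ValueError):
    """A coordinate channel has zero second moment, so relative accuracy
    is undefined for it."""


class InsufficientSamplesError(CnMotionError, ValueError):
    """Fewer samples than required (e.g. a segment shorter than the
    satellite count)."""


class SmallSampleError(CnMotionError, ValueError):
    """AICc is undefined: the sample size does not exceed the parameter
    count plus one."""


class ConstructionError(CnMotionError, RuntimeError):
    """Numeric calibration of the switching module failed within the
    search budget."""


class ParseError(CnMotionError, ValueError):
    """A marker or model file does not conform to its dialect."""


class ConfigError(CnMotionError, ValueError):
    """A search or CLI configuration is empty or contradictory."""
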