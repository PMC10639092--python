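"""Exception hierarchy for strokenet.

All errors derive from :class:`StrokenetError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class StrokenetError(Exception):
    """Base class for all strokenet errors."""


class ConfigurationError(StrokenetError, ValueError):
    """An invalid configuration field; the message names the field."""


class InputLengthError(StrokenetError, ValueError):
    """A time series is too short for the requested operation."""


class SamplingRateError(StrokenetError, ValueError):
    """A filter band is incompatible with the sampling rate (Nyquist)."""


class DataAlignmentError(StrokenetError, ValueError):
    """Two data structures that must align (subjects, nodes, lengths) do not."""


class DegenerateInputError(StrokenetError, ValueError):
    """Input is degenerate for the requested statistic (zero variance,
    edgeless graph, zero marginal, ...)."""


class DesignMatrixError(StrokenetError, ValueError):
    """A regression design matrix is rank deficient / collinear."""


class InternalError(StrokenetError, RuntimeError):
    """An internal consistency check failed (should never happen)."""
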