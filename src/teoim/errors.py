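"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`TeoimError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class TeoimError(Exception):
    """Base class for all errors raised by teoim."""


class ParameterError(TeoimError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class GridMismatchError(TeoimError, ValueError):
    """Two images that must share a grid do not."""


class ConfigError(TeoimError, ValueError):
    """A configuration file or mapping failed strict validation."""


class FitError(TeoimError, RuntimeError):
    """A model fit failed to converge; carries solver diagnostics in args."""


class DegenerateDataError(FitError):
    """The data carry no usable signal for the requested fit."""
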