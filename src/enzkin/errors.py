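"""Exception hierarchy for the kinetics pipeline.

All errors derive from :class:`EnzkinError` so callers can catch the
package's failures with a single except clause while still letting
programming errors (TypeError etc.) propagate.
"""


class EnzkinError(Exception):
    """Base class for all package-specific errors."""


class ParameterMismatchError(EnzkinError, ValueError):
    """Kinetic parameters do not match the requested mechanism."""


class DomainError(EnzkinError, ValueError):
    """An input value is outside its physical domain (e.g. S <= 0)."""


class InsufficientDataError(EnzkinError, ValueError):
    """Too few observations for the requested operation."""


class UnidentifiableError(EnzkinError, ValueError):
    """The data carry no information about a requested parameter."""


class NestingError(EnzkinError, ValueError):
    """An F test was requested for a non-nested model pair."""


class DegenerateControlError(EnzkinError, ValueError):
    """Control velocity is non-positive; percent inhibition undefined."""


class ConfigError(EnzkinError, ValueError):
    """Invalid run configuration."""


class PlateParseError(EnzkinError, ValueError):
    """Malformed plate or layout CSV."""


class UnknownCompoundError(EnzkinError, KeyError):
    """Compound label has no recorded assay protocol."""


class SelectionError(EnzkinError, RuntimeError):
    """Model selection could not be completed (e.g. non-converged fit)."""
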