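"""Exception hierarchy for thermokin.

All domain errors derive from :class:`ThermokinError` so callers (and the
CLI) can catch validation problems without masking programming errors.
"""


class ThermokinError(Exception):
    """Base class for all thermokin domain errors."""


class ValidationError(ThermokinError, ValueError):
    """An input violated a documented invariant."""


class InsufficientDataError(ValidationError):
    """Too few usable points to perform a fit."""


class UnfittedModelError(ThermokinError, RuntimeError):
    """A model was queried before being fitted."""
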